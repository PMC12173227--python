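"""Synthetic ground-truth cohorts with a controlled asymmetry knob.

Real resting-state cohorts are replaced by generated ones: a symmetric
structural scaffold (connected Erdos-Renyi mask), per-subject directed
ground-truth couplings whose directional asymmetry is set by a knob
kappa in [0, 1], and band-limited oscillatory panels simulated from
those couplings with the nonlinear Hopf network.

Asymmetry is injected as balanced +/- splits around a shared base weight
(w_ij = w(1 + kappa*u), w_ji = w(1 - kappa*u), u ~ U(0, 1)), so the total
coupling mass of a pair is kappa-invariant: groups differ in
directionality, not in overall coupling strength — the mechanism under
study, isolated.  kappa = 0 gives perfectly symmetric (equilibrium)
models; kappa = 1 maximally asymmetric ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .core import CouplingMatrix, SignalPanel
from .hopf import HopfParams, simulate
from .linear_hopf import StabilityError, build_linear_model

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_mask",
    "generate_ground_truth",
    "generate_cohort",
    "write_cohort",
    "read_cohort_panels",
]

log = logging.getLogger(__name__)

# Frequency band the generated oscillators live in (Hz): the slow
# hemodynamic band the empirical pipeline isolates.
F_LOW, F_HIGH = 0.04, 0.07
DEFAULT_A = -0.02
DEFAULT_BETA = 0.02


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    kappa: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("group needs at least one subject")
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort.

    Defaults emulate a resting-state dataset of the sleep-study scale:
    90 regions sampled every ~2 s for 1505 volumes.  ``weight_scale``
    sets the base coupling strength; 0.05 keeps even maximally
    asymmetric weights well below the fitting weight cap (0.2) with
    headroom to spare.
    """

    groups: tuple[GroupSpec, ...]
    n_regions: int = 90
    tr: float = 2.0
    n_samples: int = 1505
    mask_density: float = 0.3
    weight_scale: float = 0.05
    mask_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not self.groups:
            raise ValueError("need at least one group")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class GroundTruth:
    """A known generating model for one synthetic subject."""

    gec: CouplingMatrix
    kappa: float
    params: HopfParams
    subject_id: str = ""
    state_label: str = ""


def generate_mask(
    n_regions: int,
    density: float,
    seed: int,
    weight_scale: float = 1.0,
    max_retries: int = 50,
) -> CouplingMatrix:
    """Connected symmetric Erdos-Renyi scaffold with uniform base weights.

    Edges are drawn i.i.d. at the requested density on the upper
    triangle and mirrored; draws are repeated (bounded) until the graph
    is connected, mirroring the single connected structural connectome
    the fitting starts from.
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        upper = rng.random((n_regions, n_regions)) < density
        mask = np.triu(upper, k=1)
        mask = mask | mask.T
        n_comp, _ = connected_components(mask, directed=False)
        if n_comp == 1:
            return CouplingMatrix(
                weights=weight_scale * mask.astype(float), mask=mask
            )
    raise ValueError(
        f"could not draw a connected mask at density {density} "
        f"in {max_retries} tries"
    )


def generate_ground_truth(
    mask: CouplingMatrix,
    kappa: float,
    weight_scale: float,
    seed: int,
    tr: float = 2.0,
    max_rescales: int = 10,
) -> GroundTruth:
    """Directed ground-truth coupling with asymmetry knob ``kappa``.

    Per masked pair a base weight ``w ~ U(0.5, 1) * weight_scale`` is
    split into ``w(1 +/- kappa*u)``, ``u ~ U(0, 1)``, assigning the larger
    direction at random.  Intrinsic frequencies are drawn uniformly in
    the 0.04-0.07 Hz band.  If the linearized model were unstable the
    weights are rescaled down (never triggered for diffusive nonnegative
    coupling, kept as a guard).
    """
    if not 0 <= kappa <= 1:
        raise ValueError("kappa must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = mask.n_regions
    iu, ju = np.where(np.triu(mask.mask, k=1))
    w_base = rng.uniform(0.5, 1.0, size=iu.size) * weight_scale
    u = rng.uniform(0.0, 1.0, size=iu.size)
    # the stronger direction consistently points up the node ordering,
    # giving the network a coherent directional hierarchy; incoherent
    # (randomly oriented) pair asymmetries largely cancel at network
    # scale and produce almost no net probability flux
    weights = np.zeros((n, n))
    weights[iu, ju] = w_base * (1 + kappa * u)
    weights[ju, iu] = w_base * (1 - kappa * u)

    omega = 2 * np.pi * rng.uniform(F_LOW, F_HIGH, size=n)
    scale = 1.0
    for attempt in range(max_rescales):
        gec = CouplingMatrix(weights=scale * weights, mask=mask.mask.copy())
        params = HopfParams(
            a=DEFAULT_A,
            omega=omega,
            C=gec,
            G=1.0,
            beta=DEFAULT_BETA,
            tr=tr,
            seed=int(rng.integers(2**31)),
        )
        try:
            build_linear_model(params)
            break
        except StabilityError:
            scale *= 0.8
            log.warning("ground truth unstable; rescaling weights by %.3g", scale)
    else:
        raise StabilityError("ground truth unstable after rescaling retries")
    return GroundTruth(gec=gec, kappa=kappa, params=params)


def generate_cohort(spec: CohortSpec) -> list[tuple[GroundTruth, SignalPanel]]:
    """One ground truth and one simulated panel per subject.

    All subjects share the cohort mask (as all real subjects share the
    healthy structural connectome); every subject gets an independent
    ground truth at its group's kappa and an independent noise seed, all
    derived deterministically from the group seeds.
    """
    mask = generate_mask(spec.n_regions, spec.mask_density, spec.mask_seed)
    out: list[tuple[GroundTruth, SignalPanel]] = []
    for group in spec.groups:
        for s in range(group.n_subjects):
            subj_seed = int(
                np.random.SeedSequence([group.seed, s]).generate_state(1)[0]
                % 2**31
            )
            gt = generate_ground_truth(
                mask, group.kappa, spec.weight_scale, subj_seed, tr=spec.tr
            )
            gt.subject_id = f"{group.label}-{s:02d}"
            gt.state_label = group.label
            panel = simulate(
                gt.params,
                spec.n_samples,
                subject_id=gt.subject_id,
                state_label=group.label,
            )
            out.append((gt, panel))
    return out


def write_cohort(
    cohort: list[tuple[GroundTruth, SignalPanel]],
    outdir: str | Path,
    spec: CohortSpec | None = None,
) -> None:
    """Write panels as TSVs plus a JSON manifest (and ground-truth gECs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for gt, panel in cohort:
        panel.to_tsv(outdir / f"{panel.subject_id}.tsv")
        gt.gec.to_tsv(
            outdir / f"{panel.subject_id}.gec.tsv",
            kappa=gt.kappa,
            subject_id=gt.subject_id,
        )
        manifest.append(
            {
                "subject_id": panel.subject_id,
                "group": panel.state_label,
                "kappa": gt.kappa,
                "seed": gt.params.seed,
                "tr": panel.tr,
            }
        )
    doc = {"subjects": manifest}
    if spec is not None:
        doc["spec"] = {
            "n_regions": spec.n_regions,
            "tr": spec.tr,
            "n_samples": spec.n_samples,
            "mask_density": spec.mask_density,
            "weight_scale": spec.weight_scale,
            "mask_seed": spec.mask_seed,
            "groups": [
                {
                    "label": g.label,
                    "n_subjects": g.n_subjects,
                    "kappa": g.kappa,
                    "seed": g.seed,
                }
                for g in spec.groups
            ],
        }
    (outdir / "manifest.json").write_text(json.dumps(doc, indent=1))


def read_cohort_panels(indir: str | Path) -> list[SignalPanel]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    return [
        SignalPanel.from_tsv(indir / f"{entry['subject_id']}.tsv")
        for entry in manifest["subjects"]
    ]
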
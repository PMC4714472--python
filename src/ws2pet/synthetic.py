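"""Synthetic brain phantoms and test-retest cohorts with a linked pseudo-CSF.

The phantom is a coarse geometric brain on an isotropic grid (default
64^3 voxels at 2 mm):

* a spherical cerebral gray-matter shell (the target region),
* a white-matter core with a graded-probability rim (prob 1.0 core,
  0.3 rim) so the 10 %/100 % threshold masks genuinely differ,
* a corpus-callosum patch carved out of the WM core,
* detached cerebellar gray matter and brainstem spheres below the brain.

Focal uptake ("plaques") is modelled as Gaussian blobs restricted to the
gray-matter shell; additive Gaussian noise is applied inside tissue only.
Compartment baselines default to a florbetapir-like contrast (hot white
matter from nonspecific binding, cooler gray matter).

Cohorts emulate a test-retest design: each subject has a stable amyloid
burden driving blob amplitude; the follow-up scan re-draws noise and
applies a small multiplicative drift to reference-tissue activity.  The
pseudo-CSF biomarker is inversely linked to burden, either linearly or
through a plateau (high plateau at low burden, low plateau above a
threshold), plus a per-subject biological scatter and a per-visit assay
noise.

What the generator does NOT emulate: PET physics (point-spread, scatter,
attenuation), anatomical variability, and partial-volume mixing beyond
the single graded WM rim.  Passing tests on these phantoms therefore
validate the estimators, not scanner realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Volume
from .masks import TissueProbabilityMap

#: Atlas label ids written by the phantom generator.
LABEL_IDS = {
    "target_gm": 1,
    "cereb_gm": 2,
    "wm": 3,
    "brainstem": 4,
    "corpus_callosum": 5,
}

#: Reference-tissue compartments (everything except the target shell).
REFERENCE_COMPARTMENTS = (
    "cereb_gm", "wm_core", "wm_rim", "brainstem", "corpus_callosum",
)


class PhantomError(ValueError):
    """Raised for geometrically impossible phantom specifications."""


def _default_activity() -> dict[str, float]:
    # florbetapir-like contrast, arbitrary activity units
    return {
        "target_gm": 1.0,
        "cereb_gm": 1.0,
        "wm_core": 1.6,
        "wm_rim": 1.3,      # partial-volume-like GM/WM mix at the border
        "brainstem": 1.5,
        "corpus_callosum": 1.7,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity, focal-uptake and noise parameters of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    activity: dict[str, float] = field(default_factory=_default_activity)
    n_blobs: int = 6
    blob_amplitude: float = 0.8
    blob_sigma_mm: float = 5.0
    noise_sd: float = 0.05
    #: If set, the GM-shell baseline is shifted (pre-noise) so the shell
    #: mean equals this value; isolates heterogeneity from total uptake.
    target_mean: float | None = None
    seed: int = 0
    #: Separate noise stream so test-retest pairs can share blob anatomy
    #: while re-drawing noise; defaults to ``seed``.
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise PhantomError(
                f"grid too small for the phantom geometry: {self.shape}"
            )
        if self.n_blobs < 0 or self.blob_sigma_mm <= 0 or self.noise_sd < 0:
            raise PhantomError("invalid blob/noise parameters")


@dataclass
class Phantom:
    """Generated phantom: PET volume, probability maps, atlas, truth masks."""

    pet: Volume
    tpm: TissueProbabilityMap
    labels: Volume
    compartments: dict[str, np.ndarray]
    spec: PhantomSpec


def _sphere(shape, center_frac, radius_frac) -> np.ndarray:
    shape = np.asarray(shape)
    center = center_frac * shape
    radius = radius_frac * shape.min()
    grid = np.indices(tuple(shape)) + 0.5
    d2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def _shell(shape, center_frac, inner_frac, outer_frac) -> np.ndarray:
    return _sphere(shape, center_frac, outer_frac) & ~_sphere(
        shape, center_frac, inner_frac)


def compartment_masks(shape) -> dict[str, np.ndarray]:
    """Disjoint tissue compartments of the fixed phantom geometry."""
    shape = tuple(shape)
    brain = np.array([0.5, 0.5, 0.5625])
    target_gm = _shell(shape, brain, 0.328, 0.375)
    wm_rim = _shell(shape, brain, 0.281, 0.305)
    wm_all = _sphere(shape, brain, 0.281)
    # corpus callosum: elongated box carved out of the WM core
    cc = np.zeros(shape, dtype=bool)
    c = (brain * np.asarray(shape)).astype(int)
    hx = max(2, int(0.094 * shape[0]))
    hy = max(1, int(0.031 * shape[1]))
    hz = max(1, int(0.031 * shape[2]))
    cc[c[0] - hx:c[0] + hx, c[1] - hy:c[1] + hy, c[2] - hz:c[2] + hz] = True
    cc &= wm_all
    wm_core = wm_all & ~cc
    cereb_gm = _sphere(shape, np.array([0.5, 0.25, 0.094]), 0.078)
    brainstem = _sphere(shape, np.array([0.5, 0.6875, 0.094]), 0.0625)

    comp = {
        "target_gm": target_gm,
        "wm_core": wm_core,
        "wm_rim": wm_rim,
        "corpus_callosum": cc,
        "cereb_gm": cereb_gm,
        "brainstem": brainstem,
    }
    total = np.zeros(shape, dtype=np.int32)
    for mask in comp.values():
        total += mask
    if total.max() > 1:
        raise PhantomError("phantom compartments overlap")
    for name, mask in comp.items():
        if not mask.any():
            raise PhantomError(f"compartment {name!r} is empty on grid {shape}")
    return comp


def gaussian_blob_field(shape, spacing, centers, amplitude: float,
                        sigma_mm: float) -> np.ndarray:
    """Sum of isotropic Gaussian bumps (evaluated on a 4-sigma window each)."""
    spacing = np.asarray(spacing, dtype=float)
    out = np.zeros(shape, dtype=float)
    reach = np.ceil(4.0 * sigma_mm / spacing).astype(int)
    for center in np.atleast_2d(centers):
        lo = np.maximum(center - reach, 0)
        hi = np.minimum(center + reach + 1, shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grid = np.indices([b - a for a, b in zip(lo, hi)])
        d2 = sum(((grid[i] + lo[i] - center[i]) * spacing[i]) ** 2
                 for i in range(3))
        out[sl] += amplitude * np.exp(-d2 / (2.0 * sigma_mm**2))
    return out


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom; deterministic given the spec's seeds."""
    rng = np.random.default_rng(spec.seed)
    comp = compartment_masks(spec.shape)
    act = {**_default_activity(), **spec.activity}

    pet = np.zeros(spec.shape, dtype=float)
    for name, mask in comp.items():
        pet[mask] = act[name]

    tg = comp["target_gm"]
    if spec.n_blobs > 0 and spec.blob_amplitude != 0:
        gm_voxels = np.argwhere(tg)
        centers = gm_voxels[
            rng.choice(len(gm_voxels), size=spec.n_blobs, replace=False)
        ]
        field_ = gaussian_blob_field(
            spec.shape, spec.spacing, centers,
            spec.blob_amplitude, spec.blob_sigma_mm,
        )
        pet[tg] += field_[tg]
    if spec.target_mean is not None:
        pet[tg] += spec.target_mean - pet[tg].mean()

    tissue = np.zeros(spec.shape, dtype=bool)
    for mask in comp.values():
        tissue |= mask
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(
            spec.seed if spec.noise_seed is None else spec.noise_seed
        )
        pet[tissue] += noise_rng.normal(0.0, spec.noise_sd, int(tissue.sum()))

    gm_prob = np.zeros(spec.shape, dtype=float)
    gm_prob[comp["target_gm"] | comp["cereb_gm"]] = 1.0
    wm_prob = np.zeros(spec.shape, dtype=float)
    wm_prob[comp["wm_core"] | comp["corpus_callosum"]] = 1.0
    wm_prob[comp["wm_rim"]] = 0.3

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[comp["target_gm"]] = LABEL_IDS["target_gm"]
    labels[comp["cereb_gm"]] = LABEL_IDS["cereb_gm"]
    labels[comp["wm_core"] | comp["wm_rim"]] = LABEL_IDS["wm"]
    labels[comp["brainstem"]] = LABEL_IDS["brainstem"]
    labels[comp["corpus_callosum"]] = LABEL_IDS["corpus_callosum"]

    affine = np.diag([*spec.spacing, 1.0])
    return Phantom(
        pet=Volume(pet, affine),
        tpm=TissueProbabilityMap(gm_prob=gm_prob, wm_prob=wm_prob),
        labels=Volume(labels, affine),
        compartments=comp,
        spec=spec,
    )


def apply_reference_drift(phantom: Phantom, factor: float) -> Phantom:
    """Scale all reference-tissue activity by ``factor`` (target untouched).

    Models a visit-to-visit shift in nonspecific reference uptake — the
    perturbation against which wS2 is expected to be more robust than the
    SUVR mean.
    """
    pet = phantom.pet.data.copy()
    for name in REFERENCE_COMPARTMENTS:
        pet[phantom.compartments[name]] *= factor
    return Phantom(
        pet=phantom.pet.with_data(pet),
        tpm=phantom.tpm,
        labels=phantom.labels,
        compartments=phantom.compartments,
        spec=phantom.spec,
    )


# ---------------------------------------------------------------------------
# cohorts

TIMEPOINTS = ("baseline", "followup")


@dataclass(frozen=True)
class CohortSpec:
    """Test-retest cohort with a burden-linked pseudo-CSF biomarker.

    Defaults are chosen so the simulated cohort resembles an LMCI-like
    test-retest sample: n = 21 subjects, cross-sectional CSF spread of
    roughly 165 +/- 45 pg/ml, per-visit assay noise giving a test-retest
    CSF CV of a few percent, and a stable per-subject burden so no true
    longitudinal change occurs.

    link: ``"linear"`` -> biomarker = a - b * burden; ``"plateau"`` ->
    high plateau below ``plateau_threshold``, low plateau above (the
    saturating CSF-vs-SUVR pattern seen with cerebellar normalization).
    Both links add per-subject scatter ``link_sd`` and per-visit noise
    ``biomarker_noise_sd``.
    """

    n_subjects: int = 21
    burden_mean: float = 0.5
    burden_sd: float = 0.38
    link: str = "linear"
    intercept_a: float = 220.0       # pg/ml
    slope_b: float = 110.0           # pg/ml per unit burden
    plateau_threshold: float = 0.5
    plateau_high: float = 200.0      # pg/ml
    plateau_low: float = 125.0       # pg/ml
    link_sd: float = 20.0            # per-subject biological scatter, pg/ml
    biomarker_noise_sd: float = 5.0  # per-visit assay noise, pg/ml
    #: Diffuse cortical uptake added to the GM baseline per unit burden
    #: (activity units); with the focal blobs this puts the cerebellar-
    #: normalized SUVR of the cohort in the 1.1-2.0 range typical of
    #: florbetapir LMCI data.
    diffuse_uptake: float = 0.9
    #: SD of the multiplicative reference-tissue drift at follow-up.
    ref_drift_sd: float = 0.02
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise PhantomError("cohort needs at least 3 subjects")
        if self.link not in ("linear", "plateau"):
            raise PhantomError(f"unknown biomarker link {self.link!r}")


def _link_value(spec: CohortSpec, burden: float) -> float:
    if spec.link == "linear":
        return spec.intercept_a - spec.slope_b * burden
    return spec.plateau_high if burden < spec.plateau_threshold \
        else spec.plateau_low


def expected_spearman_linear(spec: CohortSpec) -> float:
    """Population Spearman rho of (burden, biomarker) under the linear link.

    Burden and the two noise terms are Gaussian, so the pair is bivariate
    normal with Pearson correlation r = -b*s_x / sqrt(b^2 s_x^2 + s_e^2),
    and rho_S = (6/pi) * arcsin(r/2).
    """
    if spec.link != "linear":
        raise PhantomError("closed form only available for the linear link")
    sig = spec.slope_b * spec.burden_sd
    noise = np.hypot(spec.link_sd, spec.biomarker_noise_sd)
    r = -sig / np.hypot(sig, noise)
    return float(6.0 / np.pi * np.arcsin(r / 2.0))


def _draw_subjects(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(spec.n_subjects):
        burden = rng.normal(spec.burden_mean, spec.burden_sd)
        eta = rng.normal(0.0, spec.link_sd)
        drift = rng.normal(1.0, spec.ref_drift_sd)
        for tp in TIMEPOINTS:
            eps = rng.normal(0.0, spec.biomarker_noise_sd)
            rows.append({
                "subject_id": f"sub{i + 1:02d}",
                "timepoint": tp,
                "burden": burden,
                "biomarker": _link_value(spec, burden) + eta + eps,
                "ref_drift": drift if tp == "followup" else 1.0,
            })
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """Volume-level cohort: one phantom per subject-timepoint + biomarkers."""

    phantoms: dict[tuple[str, str], Phantom]
    biomarker: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate phantom volumes for every subject and timepoint.

    Per subject: blob anatomy (centers, amplitude = burden) is shared
    between baseline and follow-up; noise is re-drawn per visit and the
    follow-up applies the subject's multiplicative reference drift.
    Negative burden draws are clipped to zero amplitude (no focal uptake).
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_subjects(spec, rng)
    phantoms: dict[tuple[str, str], Phantom] = {}
    for (sid,), sub in truth.groupby(["subject_id"], sort=True):
        burden = float(sub["burden"].iloc[0])
        anat_seed = int(rng.integers(0, 2**31))
        activity = {**_default_activity(), **spec.phantom.activity}
        activity["target_gm"] += spec.diffuse_uptake * max(burden, 0.0)
        for tp in TIMEPOINTS:
            noise_seed = int(rng.integers(0, 2**31))
            pspec = replace(
                spec.phantom,
                activity=activity,
                blob_amplitude=max(burden, 0.0) * spec.phantom.blob_amplitude,
                seed=anat_seed,
                noise_seed=noise_seed,
            )
            ph = make_phantom(pspec)
            if tp == "followup":
                drift = float(
                    sub.loc[sub["timepoint"] == tp, "ref_drift"].iloc[0]
                )
                ph = apply_reference_drift(ph, drift)
            phantoms[(sid, tp)] = ph
    biomarker = truth[["subject_id", "timepoint", "biomarker"]].copy()
    return Cohort(phantoms=phantoms, biomarker=biomarker, truth=truth,
                  spec=spec)


#: Monotone scheme-specific maps from burden to SUVR used by the
#: record-level simulator (intercept, slope); ordered like real
#: florbetapir contrast (cerebellar normalization -> largest SUVR).
_SCHEME_SUVR_PARAMS = {
    "cereb_gm": (1.10, 0.90),
    "wm10": (0.85, 0.65),
    "wm100": (0.70, 0.55),
    "brainstem": (0.75, 0.60),
    "corpus_callosum": (0.62, 0.50),
}


def make_cohort_records(spec: CohortSpec,
                        rng: np.random.Generator | None = None,
                        outcome_noise_sd: float = 0.0) -> pd.DataFrame:
    """Record-level cohort: SubjectRecord table without image simulation.

    PET outcomes are strictly monotone functions of the latent burden
    (plus optional measurement noise), so rank statistics against the
    biomarker coincide with those of burden itself.  This is the fast
    route for replicate-heavy statistical validation of the cohort layer;
    :func:`make_cohort` exercises the full image pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = _draw_subjects(spec, rng)
    rows = []
    for _, r in truth.iterrows():
        for scheme, (a0, a1) in _SCHEME_SUVR_PARAMS.items():
            burden = r["burden"]
            jitter = (rng.normal(0.0, outcome_noise_sd, size=3)
                      if outcome_noise_sd > 0 else np.zeros(3))
            rows.append({
                "subject_id": r["subject_id"],
                "timepoint": r["timepoint"],
                "scheme": scheme,
                "suvr_mean": a0 + a1 * burden + jitter[0],
                "suvr_median": 0.97 * a0 + 0.9 * a1 * burden + jitter[1],
                "ws2_auc": 9.0 * (a0 + 1.1 * a1 * burden) + jitter[2],
                "biomarker": r["biomarker"],
            })
    return pd.DataFrame(rows)
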
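"""Synthetic inputs with known ground truth.

Three generators back the test suite and any offline demonstration run:

* deterministic fractal fixtures with closed-form box-counting dimension,
* rasterized vessel networks with exact pixel counts and per-branch
  arc/chord ratios,
* two-group cohorts whose group means/SDs and category proportions default
  to the study's published summary table.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .cohort_stats import IMPROVED, NOT_IMPROVED, EyeRecord
from .morphometry import BiomarkerSet

__all__ = [
    "FractalFixture",
    "VesselNetworkSpec",
    "VesselNetwork",
    "GroupParams",
    "CohortSpec",
    "SyntheticError",
    "make_fractal",
    "make_vessel_network",
    "make_cohort",
    "null_cohort_spec",
]


class SyntheticError(ValueError):
    """Raised for infeasible generator specifications."""


# ---------------------------------------------------------------------------
# fractal fixtures
# ---------------------------------------------------------------------------

_KNOWN_DIMENSION = {
    "line": 1.0,
    "filled_square": 2.0,
    "sierpinski": math.log(3) / math.log(2),
    "koch": math.log(4) / math.log(3),
}


@dataclass(frozen=True)
class FractalFixture:
    """A named fractal pattern with closed-form box-counting dimension."""

    kind: str  # line | filled_square | sierpinski | koch
    depth: int = 7

    def __post_init__(self) -> None:
        if self.kind not in _KNOWN_DIMENSION:
            raise SyntheticError(f"unknown fractal kind {self.kind!r}")
        if self.depth < 1:
            raise SyntheticError("depth must be >= 1")

    @property
    def known_dimension(self) -> float:
        return _KNOWN_DIMENSION[self.kind]


def make_fractal(fixture: FractalFixture, size: int | None = None) -> np.ndarray:
    """Rasterize the fixture as a boolean mask.

    ``sierpinski`` uses the bitwise construction on a 2**depth grid, so the
    foreground count is exactly 3**depth and every power-of-two box count is
    exact.  ``koch`` draws the depth-d curve on a 3**depth-wide grid.
    """
    kind, depth = fixture.kind, fixture.depth
    if kind == "line":
        n = size or 256
        out = np.zeros((n, n), dtype=bool)
        out[n // 2, :] = True
        return out
    if kind == "filled_square":
        n = size or 256
        return np.ones((n, n), dtype=bool)
    if kind == "sierpinski":
        if depth > 12:
            raise SyntheticError("sierpinski depth too deep for raster")
        n = 2**depth
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return (i & j) == 0
    # koch curve
    if depth > 6:
        raise SyntheticError("koch depth too deep for raster")
    pts = [np.array([0.0, 0.0]), np.array([1.0, 0.0])]
    rot = np.array(
        [[math.cos(math.pi / 3), -math.sin(math.pi / 3)],
         [math.sin(math.pi / 3), math.cos(math.pi / 3)]]
    )
    for _ in range(depth):
        new = []
        for p, q in zip(pts[:-1], pts[1:]):
            d = (q - p) / 3.0
            peak = p + d + rot @ d
            new.extend([p, p + d, peak, p + 2 * d])
        new.append(pts[-1])
        pts = new
    n = 3**depth
    out = np.zeros((n // 2 + 2, n + 1), dtype=bool)
    scale = n
    for p, q in zip(pts[:-1], pts[1:]):
        length = max(2, int(np.linalg.norm(q - p) * scale * 2))
        ts = np.linspace(0.0, 1.0, length)
        xs = np.clip((p[0] + ts * (q[0] - p[0])) * scale, 0, out.shape[1] - 1)
        ys = np.clip((p[1] + ts * (q[1] - p[1])) * scale, 0, out.shape[0] - 1)
        out[ys.astype(int), xs.astype(int)] = True
    return out


# ---------------------------------------------------------------------------
# vessel networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselNetworkSpec:
    """Parameters of a drawn vessel network.

    Branches are thick sinusoidally perturbed strokes laid out in disjoint
    horizontal bands, so the drawn mask, centerline and per-branch arc/chord
    ratios are known exactly.
    """

    image_size: int = 256
    n_branches: int = 5
    thickness: int = 3
    wiggle_amplitude: float = 4.0
    wiggle_cycles: float = 2.0
    loop_probability: float = 0.0
    background_mean: float = 30.0
    vessel_mean: float = 220.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise SyntheticError("thickness must be >= 1")
        if not (0.0 <= self.loop_probability <= 1.0):
            raise SyntheticError("loop_probability must lie in [0, 1]")
        for name in ("background_mean", "vessel_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise SyntheticError(f"{name} must lie in [0, 255]")
        band = self.image_size // max(1, self.n_branches)
        if band < 2 * self.wiggle_amplitude + self.thickness + 4:
            raise SyntheticError(
                "branches do not fit disjoint bands; reduce n_branches, "
                "amplitude or thickness"
            )


@dataclass(frozen=True)
class VesselNetwork:
    """Generator output: noisy image, exact mask, and ground truth."""

    image: np.ndarray  # uint8 grayscale
    mask: np.ndarray  # exact drawn vessel mask
    centerline: np.ndarray  # exact drawn centerline pixels
    branch_ratios: tuple[float, ...]  # per-branch arc/chord from the polyline
    n_branches: int
    n_loops: int

    @property
    def vessel_pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def centerline_length(self) -> float:
        return float(self.centerline.sum())  # 1-px pixels as a length proxy

    @property
    def mean_tortuosity(self) -> float:
        return float(np.mean(self.branch_ratios)) if self.branch_ratios else math.nan


def _stroke(center_rc: np.ndarray, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Thicken a centerline point chain with a disk structuring element."""
    mask = np.zeros(shape, dtype=bool)
    mask[center_rc[:, 0], center_rc[:, 1]] = True
    if radius > 0:
        yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
        selem = yy**2 + xx**2 <= radius**2
        mask = ndimage.binary_dilation(mask, structure=selem)
    return mask


def make_vessel_network(spec: VesselNetworkSpec) -> VesselNetwork:
    """Draw the network and return it with exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    band = S // spec.n_branches
    margin = spec.thickness + 2
    radius = spec.thickness // 2

    mask = np.zeros((S, S), dtype=bool)
    centerline = np.zeros((S, S), dtype=bool)
    ratios: list[float] = []
    n_loops = 0

    for i in range(spec.n_branches):
        y0 = i * band + band // 2
        if spec.loop_probability > 0 and rng.random() < spec.loop_probability:
            # closed elliptical loop (chord 0; excluded from tortuosity)
            cx = S / 2 + rng.uniform(-S / 8, S / 8)
            a = (S - 2 * margin) / 2.5
            b = max(3.0, band / 2.0 - margin)
            t = np.linspace(0, 2 * math.pi, int(4 * math.pi * a), endpoint=False)
            xs = cx + a * np.cos(t)
            ys = y0 + b * np.sin(t)
            n_loops += 1
            ratio = None
        else:
            phase = rng.uniform(0, 2 * math.pi)
            L = S - 2 * margin
            xs = np.linspace(margin, S - margin - 1, 4 * L)
            arg = 2 * math.pi * spec.wiggle_cycles * (xs - xs[0]) / L + phase
            ys = y0 + spec.wiggle_amplitude * np.sin(arg)
            arc = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
            chord = float(math.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
            ratio = arc / chord
        rc = np.unique(
            np.stack([np.clip(np.round(ys), 0, S - 1),
                      np.clip(np.round(xs), 0, S - 1)], axis=1).astype(int),
            axis=0,
        )
        centerline[rc[:, 0], rc[:, 1]] = True
        mask |= _stroke(rc, (S, S), radius)
        if ratio is not None:
            ratios.append(ratio)

    image = np.full((S, S), spec.background_mean, dtype=float)
    image[mask] = spec.vessel_mean
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    return VesselNetwork(
        image=image,
        mask=mask,
        centerline=centerline,
        branch_ratios=tuple(ratios),
        n_branches=spec.n_branches,
        n_loops=n_loops,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Per-group distribution parameters for one outcome group."""

    continuous: dict[str, tuple[float, float]]  # name -> (mean, sd)
    proportions: dict[str, float]  # name -> P(level coded 1)

    def __post_init__(self) -> None:
        for name, (mean, sd) in self.continuous.items():
            if sd <= 0:
                raise SyntheticError(f"{name}: sd must be > 0")
        for name, p in self.proportions.items():
            if not (0.0 <= p <= 1.0):
                raise SyntheticError(f"{name}: proportion must lie in [0, 1]")


# truncation bounds keeping synthetic records physiologically possible
_BOUNDS = {
    "age": (18.0, 100.0),
    "axial_length": (20.0, 36.0),
    "spherical_equivalent": (-30.0, 5.0),
    "bcva_baseline": (0.0, 100.0),
    "bcva_12m": (0.0, 100.0),
    "sfct": (10.0, 400.0),
    "cft": (50.0, 800.0),
    "cnv_size": (0.01, 5.0),
    "vessel_density": (1.0, 100.0),
    "vessel_length_density": (0.5, 80.0),
    "vessel_diameter_index": (1.0, 8.0),
    "vessel_tortuosity": (1.0, 2.0),
    "fractal_dimension": (0.8, 2.0),
    "lacunarity": (0.0, 2.0),
    "n_injections": (0.0, 20.0),
}

# published per-group summaries: (improved, not improved)
_TABLE_CONTINUOUS = {
    "age": ((53.71, 18.98), (60.24, 15.73)),
    "axial_length": ((28.79, 1.59), (29.19, 0.94)),
    "spherical_equivalent": ((-12.18, 3.10), (-12.18, 4.45)),
    "bcva_baseline": ((49.12, 21.08), (53.53, 19.67)),
    "bcva_12m": ((72.35, 15.62), (48.82, 23.69)),
    "sfct": ((79.97, 33.15), (50.66, 18.31)),
    "cft": ((267.33, 119.62), (211.69, 82.52)),
    "cnv_size": ((0.329, 0.257), (0.481, 0.234)),
    "vessel_density": ((41.31, 13.23), (43.69, 7.66)),
    "vessel_length_density": ((21.21, 8.18), (21.75, 4.52)),
    "vessel_diameter_index": ((2.15, 0.96), (2.12, 0.62)),
    "vessel_tortuosity": ((1.22, 0.062), (1.21, 0.097)),
    "fractal_dimension": ((1.45, 0.101), (1.53, 0.082)),
    "lacunarity": ((0.367, 0.066), (0.391, 0.079)),
    "n_injections": ((2.41, 1.23), (2.76, 1.75)),
}

_TABLE_PROPORTIONS = {
    "sex_male": (2 / 17, 2 / 17),
    "ez_grade0": (10 / 17, 4 / 17),
    "elm_grade0": (11 / 17, 6 / 17),
    "srf_present": (2 / 17, 3 / 17),
    "morphology_medusa": (6 / 17, 4 / 17),
    "branching": (8 / 17, 6 / 17),
    "loops": (6 / 17, 7 / 17),
    "dark_halo": (11 / 17, 8 / 17),
}


def table_group_params(group: str) -> GroupParams:
    """Published group summaries as generator parameters."""
    idx = 0 if group == IMPROVED else 1
    return GroupParams(
        continuous={k: v[idx] for k, v in _TABLE_CONTINUOUS.items()},
        proportions={k: v[idx] for k, v in _TABLE_PROPORTIONS.items()},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-group cohort."""

    n_per_group: tuple[int, int] = (17, 17)
    improved: GroupParams = field(default_factory=lambda: table_group_params(IMPROVED))
    not_improved: GroupParams = field(
        default_factory=lambda: table_group_params(NOT_IMPROVED)
    )
    seed: int = 0
    #: when True (default) the 12-month BCVA is re-derived from a per-group
    #: letter gain so each record's gain is consistent with its label; a
    #: null-calibration spec turns this off so every variable, including the
    #: 12-month BCVA, is drawn identically in both groups.
    enforce_outcome_consistency: bool = True

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise SyntheticError("n_per_group must be >= 1 in both groups")
        if set(self.improved.continuous) != set(self.not_improved.continuous) or set(
            self.improved.proportions
        ) != set(self.not_improved.proportions):
            raise SyntheticError("the two groups must parameterize the same variables")


def null_cohort_spec(
    n_per_group: tuple[int, int] = (17, 17),
    seed: int = 0,
    binary_proportion: float = 0.35,
) -> CohortSpec:
    """Zero-effect spec: both groups share one parameter set.

    Binary proportions default to 0.35: with 17-vs-17 groups the exact null
    rejection rate of the uncorrected chi-square is 0.0492 at that marginal
    (closest to nominal), 0.0577 at 0.5, and well below 0.04 at extreme
    proportions, so a calibration spec must avoid extreme marginals.
    """
    base = table_group_params(IMPROVED)
    shared = GroupParams(
        continuous=dict(base.continuous),
        proportions={k: binary_proportion for k in base.proportions},
    )
    return CohortSpec(
        n_per_group=n_per_group,
        improved=shared,
        not_improved=shared,
        seed=seed,
        enforce_outcome_consistency=False,
    )


def _draw_continuous(rng, name: str, mean: float, sd: float, n: int) -> np.ndarray:
    lo, hi = _BOUNDS.get(name, (-np.inf, np.inf))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def make_cohort(spec: CohortSpec) -> list[EyeRecord]:
    """Draw a seed-reproducible cohort of EyeRecords.

    Continuous variables come from truncated normals at the group
    means/SDs; categorical variables are Bernoulli at the group
    proportions; the outcome label is assigned by group.  The 12-month BCVA
    is derived from the baseline so that each record's letter gain is
    consistent with its group label.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[EyeRecord] = []
    for group, params, n in (
        (IMPROVED, spec.improved, spec.n_per_group[0]),
        (NOT_IMPROVED, spec.not_improved, spec.n_per_group[1]),
    ):
        cont = {
            k: _draw_continuous(rng, k, mean, sd, n)
            for k, (mean, sd) in params.continuous.items()
        }
        cats = {k: rng.random(n) < p for k, p in params.proportions.items()}
        if group == IMPROVED:
            gain = rng.uniform(15.0, 40.0, size=n)
        else:
            gain = rng.uniform(-25.0, 14.0, size=n)
        for i in range(n):
            baseline = float(cont["bcva_baseline"][i])
            if spec.enforce_outcome_consistency:
                bcva_12m = float(np.clip(baseline + gain[i], 0.0, 100.0))
                # clipping may push a gain below threshold; nudge baseline down
                if group == IMPROVED and bcva_12m - baseline < 15.0:
                    baseline = max(0.0, bcva_12m - 15.0 - 1e-9)
            else:
                bcva_12m = float(cont["bcva_12m"][i])
            biomarkers = BiomarkerSet(
                cnv_size=float(cont["cnv_size"][i]),
                vessel_density=float(cont["vessel_density"][i]),
                vessel_length_density=min(
                    float(cont["vessel_length_density"][i]),
                    float(cont["vessel_density"][i]),
                ),
                vessel_diameter_index=float(cont["vessel_diameter_index"][i]),
                vessel_tortuosity=float(cont["vessel_tortuosity"][i]),
                fractal_dimension=float(cont["fractal_dimension"][i]),
                lacunarity=float(cont["lacunarity"][i]),
            )
            records.append(
                EyeRecord(
                    eye_id=f"{group[:3]}-{i:03d}",
                    age=float(cont["age"][i]),
                    sex="M" if cats["sex_male"][i] else "F",
                    axial_length=float(cont["axial_length"][i]),
                    spherical_equivalent=float(cont["spherical_equivalent"][i]),
                    bcva_baseline=baseline,
                    bcva_12m=bcva_12m,
                    sfct=float(cont["sfct"][i]),
                    cft=float(cont["cft"][i]),
                    ez_grade=0 if cats["ez_grade0"][i] else 1,
                    elm_grade=0 if cats["elm_grade0"][i] else 1,
                    srf_present=bool(cats["srf_present"][i]),
                    morphology="medusa_seafan" if cats["morphology_medusa"][i] else "tangled",
                    branching=bool(cats["branching"][i]),
                    loops=bool(cats["loops"][i]),
                    dark_halo=bool(cats["dark_halo"][i]),
                    n_injections=float(np.round(cont["n_injections"][i])),
                    biomarkers=biomarkers,
                    outcome=group,
                )
            )
    return records
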
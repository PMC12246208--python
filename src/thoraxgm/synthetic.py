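"""Synthetic thorax generator and fossil-style preservation masking.

The generator emulates the statistical structure the downstream analysis
assumes: a reference sample of complete, bilaterally near-symmetric ribcage
configurations with climate-group effects on overall size (centroid size)
and on the width/depth proportion, a constant caudal metamer increment down
the vertebral column, and measurement noise split into a mirror-symmetric
field plus an antisymmetric (fluctuating-asymmetry) field.

Each specimen is built as twelve planar elliptical rib arcs (half-width
``rho * b_i * C``, depth ``b_i * C``, with ``b_i`` a fixed barrel profile
peaking mid-thorax) tilted caudally by a declination angle, a vertebral
column stacked with a constant per-level increment, and a midline sternum;
the whole configuration is then scaled so its noise-free centroid size
equals the specimen's size draw ``S`` exactly.

Random draw order per specimen (one seeded generator per
:func:`generate_sample` call): size ``S``, width/depth ratio ``rho``,
declination, symmetric noise field, antisymmetric field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landmarks import CLIMATE_GROUPS, LandmarkConfiguration, SpecimenMeta
from .procrustes import centroid_size
from .reference_sample import group_sizes
from .template import MIRROR_MATRIX, Template

# canonical geometry constants (mm at unit scale, before size normalization)
_VERT_HEIGHT = 20.0     # vertebral body height (A and P)
_VERT_DEPTH = 25.0      # vertebral body antero-posterior depth
_RIB_DEPTH_SCALE = 180.0
_RIB_Y0 = -15.0         # dorsal arc start (vertebral attachment)
#: barrel profile b_i, ribs 1..12, peaking mid-thorax
_BARREL = np.array([0.50, 0.64, 0.77, 0.88, 0.96, 1.00,
                    0.99, 0.94, 0.86, 0.74, 0.60, 0.45])
_T_HEAD, _T_TUB, _T_STERN = 0.06 * np.pi, 0.18 * np.pi, 0.96 * np.pi

#: representative mean annual temperature per climate group (deg C)
GROUP_TEMPS = {"cold": 0.0, "temperate": 15.0, "warm": 26.0}


@dataclass
class ThoraxParams:
    """Generator parameters; defaults are the study-like conditions.

    Group sizes default to the reference-sample composition (cold 12,
    temperate 29, warm 18); centroid-size means (mm) to the published group
    means; ``size_cv`` to the coefficient of variation implied by the
    published group standard deviations.
    """

    n_per_group: int | Mapping[str, int] = None  # type: ignore[assignment]
    group_size_means: Mapping[str, float] = field(default_factory=lambda: {
        "cold": 2642.2, "temperate": 2662.6, "warm": 2470.8})
    size_cv: float = 0.065
    widthdepth_ratio_means: Mapping[str, float] = field(
        default_factory=lambda: {"cold": 0.75, "temperate": 0.70,
                                 "warm": 0.65})
    ratio_sd: float = 0.03
    declination_mean_deg: float = 30.0
    declination_sd_deg: float = 3.0
    vertebral_increment: Sequence[float] = (0.0, -3.0, -26.0)
    noise_sd_mm: float = 1.0
    asymmetry_sd_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group is None:
            self.n_per_group = group_sizes()
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in CLIMATE_GROUPS}
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        for g, m in self.group_size_means.items():
            if m <= 0:
                raise ValueError(f"group size mean for {g!r} must be > 0")
        for name in ("size_cv", "ratio_sd", "declination_sd_deg",
                     "noise_sd_mm", "asymmetry_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        inc = np.asarray(self.vertebral_increment, dtype=float)
        if inc.shape not in ((3,), (4, 3)):
            raise ValueError("vertebral_increment must be a 3-vector or a "
                             "(4, 3) per-corner array")
        self.vertebral_increment = inc


def _rib_angles(n_points: int = 19) -> np.ndarray:
    """Arc-angle positions: head, tubercle, 16 curve points, sternal end."""
    curve = _T_TUB + np.arange(1, n_points - 2) * \
        (_T_STERN - _T_TUB) / (n_points - 2)
    return np.concatenate([[_T_HEAD, _T_TUB], curve, [_T_STERN]])


def canonical_thorax(template: Template, rho: float,
                     declination_deg: float,
                     vertebral_increment: np.ndarray) -> np.ndarray:
    """Noise-free, exactly mirror-symmetric thorax at canonical scale.

    Returns a (k, 3) array in template order.  Raises on a degenerate
    (non-positive) rib ellipse axis.
    """
    inc = np.asarray(vertebral_increment, dtype=float)
    if inc.shape == (3,):
        inc = np.tile(inc, (4, 1))
    delta = np.deg2rad(declination_deg)
    cos_d, sin_d = np.cos(delta), np.sin(delta)

    # vertebral corner points: T1 centered at origin, constant increment
    corner_offsets = {
        "as": np.array([0.0, +_VERT_DEPTH / 2, +_VERT_HEIGHT / 2]),
        "ai": np.array([0.0, +_VERT_DEPTH / 2, -_VERT_HEIGHT / 2]),
        "ps": np.array([0.0, -_VERT_DEPTH / 2, +_VERT_HEIGHT / 2]),
        "pi": np.array([0.0, -_VERT_DEPTH / 2, -_VERT_HEIGHT / 2]),
    }
    corner_idx = {"as": 0, "ai": 1, "ps": 2, "pi": 3}
    level_z = {}   # z of each vertebral level's center
    angles = _rib_angles()
    pt_order = ["head", "tub"] + [f"c{j:02d}" for j in range(1, 17)] \
        + ["stern"]
    angle_of = dict(zip(pt_order, angles))

    def rib_point(n: int, side: str, pt: str) -> np.ndarray:
        b = _BARREL[n - 1]
        w = rho * b * _RIB_DEPTH_SCALE
        d = b * _RIB_DEPTH_SCALE
        if w <= 0 or d <= 0:
            raise ValueError(f"degenerate rib ellipse at rib {n}: "
                             f"axes w={w}, d={d}")
        t = angle_of[pt]
        z_level = float((n - 1) * inc[:, 2].mean())
        x = w * np.sin(t)
        y = _RIB_Y0 + (d / 2) * (1 - np.cos(t))
        # caudal declination tilt about the rib head's transverse axis
        y_rel = y - _RIB_Y0
        y_t = _RIB_Y0 + y_rel * cos_d
        z_t = z_level - y_rel * sin_d
        if side == "R":
            x = -x
        return np.array([x, y_t, z_t])

    coords = np.empty((len(template), 3))
    for i, e in enumerate(template.entries):
        lab = e.label
        if e.element.startswith("T") and not e.element.startswith("Th"):
            lvl = int(e.element[1:])
            corner = lab.split("_")[1]
            base = (lvl - 1) * inc[corner_idx[corner]]
            coords[i] = base + corner_offsets[corner]
            level_z[lvl] = float((lvl - 1) * inc[:, 2].mean())
        elif e.element.startswith("rib"):
            n = int(e.element[3:].split("_")[0])
            side = e.element.split("_")[1]
            pt = lab.split("_")[2]
            coords[i] = rib_point(n, side, pt)
        elif e.element == "sternum":
            j = int(lab.split("_")[1])
            s_top = rib_point(1, "L", "stern")
            s_bot = rib_point(7, "L", "stern")
            frac = (j - 1) / 21.0
            p = (1 - frac) * s_top + frac * s_bot
            coords[i] = np.array([0.0, p[1] + 10.0, p[2]])
        else:
            raise ValueError(f"unknown template element {e.element!r}")
    return coords


def _side_of(entry) -> str:
    if entry.element.startswith("rib"):
        return entry.element.split("_")[1]
    return "M"


def generate_sample(params: ThoraxParams, template: Template
                    ) -> tuple[list[LandmarkConfiguration],
                               list[SpecimenMeta]]:
    """Draw a synthetic reference sample; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    k = len(template)
    perm = template.mirror_permutation()
    sides = np.array([_side_of(e) for e in template.entries])
    left_or_mid = sides != "R"
    mid = sides == "M"

    configs: list[LandmarkConfiguration] = []
    metas: list[SpecimenMeta] = []
    sigma_ln = np.sqrt(np.log1p(params.size_cv ** 2))
    for group in CLIMATE_GROUPS:
        n = params.n_per_group.get(group, 0)
        mu = params.group_size_means[group]
        for j in range(n):
            S = float(rng.lognormal(np.log(mu) - sigma_ln ** 2 / 2,
                                    sigma_ln))
            rho = float(rng.normal(params.widthdepth_ratio_means[group],
                                   params.ratio_sd))
            decl = float(rng.normal(params.declination_mean_deg,
                                    params.declination_sd_deg))
            X = canonical_thorax(template, rho, decl,
                                 params.vertebral_increment)
            X = X * (S / centroid_size(X))

            # symmetric measurement noise: drawn on midline+left points,
            # mirrored onto the right side (zero x-noise at the midline)
            E = rng.normal(0.0, 1.0, size=(k, 3))
            sym = np.empty((k, 3))
            sym[left_or_mid] = E[left_or_mid]
            sym[mid, 0] = 0.0
            right = ~left_or_mid
            sym[right] = sym[perm[right]] @ MIRROR_MATRIX.T

            # antisymmetric (fluctuating-asymmetry) field
            A = rng.normal(0.0, 1.0, size=(k, 3))
            asym = np.empty((k, 3))
            asym[left_or_mid] = A[left_or_mid]
            asym[mid, 1:] = 0.0
            asym[right] = -(asym[perm[right]] @ MIRROR_MATRIX.T)

            X = X + params.noise_sd_mm * sym \
                + params.asymmetry_sd_mm * asym
            sid = f"{group}_{j + 1:02d}"
            configs.append(LandmarkConfiguration(
                sid, template.labels, X, np.ones(k, dtype=bool)))
            metas.append(SpecimenMeta(
                specimen_id=sid, taxon="recent_sapiens",
                climate_group=group,
                mean_annual_temp=GROUP_TEMPS[group],
                population=f"synthetic_{group}"))
    return configs, metas


@dataclass(frozen=True)
class PreservationPattern:
    """A named set of template labels retained in a fossil-like specimen."""

    name: str
    retained_labels: frozenset
    notes: tuple = ()

    def __post_init__(self) -> None:
        if not self.retained_labels:
            raise ValueError("retained label set must be nonempty")


def apply_pattern(config: LandmarkConfiguration,
                  pattern: PreservationPattern) -> LandmarkConfiguration:
    """Mask all points outside the pattern; retained coordinates untouched."""
    unknown = pattern.retained_labels - set(config.labels)
    if unknown:
        raise KeyError(f"pattern labels not in configuration: "
                       f"{sorted(unknown)[:5]}")
    keep = np.array([lab in pattern.retained_labels
                     for lab in config.labels])
    present = config.present & keep
    if not present.any():
        raise ValueError(f"pattern {pattern.name!r} retains no present "
                         "point of this configuration")
    coords = config.coords.copy()
    coords[~present] = np.nan
    return config.with_coords(coords, present=present)


def builtin_patterns(template: Template,
                     nazlet_khater_ribs: Sequence[int] = tuple(range(1, 11))
                     ) -> list[PreservationPattern]:
    """The four fossil-style preservation patterns.

    * ``complete``: everything except the rib-12 pair (fragmented).
    * ``oetzi``: as ``complete``; ribs flagged as taphonomically perturbed.
    * ``nazlet_khater_2``: vertebrae T1-T5 only, plus a configurable rib
      subset (default ribs 1-10 bilaterally); sternum not preserved.
    * ``ohalo_2``: ribs 1, 7, 9-12 bilaterally (as present in the template)
      plus vertebrae T1, T2, T3, T8; sternum not preserved.
    """
    labels = set(template.labels)

    def element_labels(elements) -> set:
        out = set()
        for el in elements:
            out |= set(template.labels_for_element(el))
        return out

    def rib_elements(numbers) -> list[str]:
        return [f"rib{n}_{s}" for n in numbers for s in ("L", "R")]

    complete = labels - element_labels(rib_elements([12]))
    nk2 = element_labels([f"T{i}" for i in range(1, 6)]) \
        | element_labels(rib_elements(nazlet_khater_ribs))
    ohalo = element_labels(["T1", "T2", "T3", "T8"]) \
        | element_labels(rib_elements([1, 7, 9, 10, 11, 12]))
    return [
        PreservationPattern("complete", frozenset(complete)),
        PreservationPattern("oetzi", frozenset(complete),
                            notes=(("perturbed_ribs", True),)),
        PreservationPattern("nazlet_khater_2", frozenset(nk2 & labels)),
        PreservationPattern("ohalo_2", frozenset(ohalo & labels)),
    ]


def one_factor_sample(template: Template, partial_labels, n: int,
                      seed: int, score_sd: float = 20.0
                      ) -> tuple[list[LandmarkConfiguration], np.ndarray,
                                 np.ndarray]:
    """Noise-free sample varying along a single latent factor.

    The factor direction is a random field projected to be orthogonal to
    the rigid motions (translations and infinitesimal rotations) of both
    the full configuration and its restriction to ``partial_labels``, so
    that form-space superimposition is exactly the identity on every
    specimen and the sample has an exactly rank-one cross-covariance
    between the two blocks.  Returns (configurations, scores, factor).
    """
    rng = np.random.default_rng(seed)
    base = canonical_thorax(template, 0.70, 30.0,
                            np.asarray([0.0, -3.0, -26.0]))
    base = base - base.mean(axis=0)
    k = len(template)
    pidx = np.array([template.index_of(lab) for lab in partial_labels])
    if len(pidx) < 4:
        raise ValueError("need at least 4 partial points")

    def rigid_basis(X: np.ndarray, rows: np.ndarray) -> list[np.ndarray]:
        vecs = []
        sub = X[rows] - X[rows].mean(axis=0)
        for a in range(3):
            t = np.zeros((k, 3))
            t[rows, a] = 1.0
            vecs.append(t.ravel())
            e = np.zeros(3)
            e[a] = 1.0
            r = np.zeros((k, 3))
            r[rows] = np.cross(e, sub)
            vecs.append(r.ravel())
        return vecs

    allrows = np.arange(k)
    constraints = np.stack(rigid_basis(base, allrows)
                           + rigid_basis(base, pidx), axis=1)
    Q, _ = np.linalg.qr(constraints)
    F = rng.normal(size=3 * k)
    F = F - Q @ (Q.T @ F)
    F = (F / np.linalg.norm(F)).reshape(k, 3)

    scores = rng.normal(0.0, score_sd, size=n)
    scores = scores - scores.mean()
    configs = [LandmarkConfiguration(
        f"factor_{i + 1:02d}", template.labels, base + t * F,
        np.ones(k, dtype=bool)) for i, t in enumerate(scores)]
    return configs, scores, F
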
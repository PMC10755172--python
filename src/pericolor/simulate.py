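"""Synthetic kernel scans and doubled-haploid populations with known truth.

Two generators stand in for the raw study material so every downstream
stage is testable end to end:

* :func:`generate_kernel_scan` draws ovoid maize kernels on a near-black
  flatbed-scanner background.  Each kernel has a body color of known hue, a
  lighter yellow "cap" band at the base (endosperm showing through), a
  darker tip zone, and optionally a notch (damaged kernel).  Touching pairs
  and small debris blobs exercise the watershed / cleaning stages.  The
  returned :class:`ImageTruth` records every kernel's parameters and the
  true label image.

* :func:`simulate_dh_population` builds a biparental DH genotype mosaic by
  a Markov chain along each chromosome (Haldane map function), assigns the
  qualitative pigment phenotype by evaluating a :class:`~pericolor.segregation.GeneticModel`
  at designated causal markers, and generates quantitative hue as
  baseline - sum(carried QTL effects) + replicate effect + residual noise,
  i.e. the line + replicate + error structure assumed by the BLUE model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qtl import DHPopulation
from .segregation import GeneticModel

__all__ = [
    "KernelSpec",
    "ImageTruth",
    "ScanSpec",
    "PlacementError",
    "generate_kernel_scan",
    "SimTruth",
    "SimulatedPopulation",
    "simulate_dh_population",
    "haldane_cm_to_recfrac",
    "body_rgb_for_hue",
]


# --------------------------------------------------------------------------
# kernel-scan images
# --------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """Raised when the requested kernels cannot be placed on the canvas."""


@dataclass(frozen=True)
class KernelSpec:
    """Ground-truth parameters of one rendered kernel."""

    center: tuple[float, float]  # (row, col)
    angle_deg: float
    length_px: float
    width_px: float
    body_rgb: tuple[float, float, float]
    cap_rgb: tuple[float, float, float] | None
    tip_rgb: tuple[float, float, float] | None
    damaged: bool


@dataclass
class ImageTruth:
    """Everything known about a generated scan."""

    kernel_count: int
    per_kernel: list[KernelSpec]
    background_rgb: tuple[float, float, float]
    debris_count: int
    labels: np.ndarray  # H x W int, 0 = background, k = kernel k
    seed: int

    def __post_init__(self) -> None:
        if self.kernel_count < 0:
            raise ValueError("kernel_count must be nonnegative")
        for k in self.per_kernel:
            if not (k.length_px >= k.width_px > 0):
                raise ValueError("each kernel needs length >= width > 0")

    def kernel_mask(self, k: int) -> np.ndarray:
        """Boolean mask of kernel ``k`` (1-based label)."""
        return self.labels == k


def body_rgb_for_hue(
    hue_deg: float, r: float = 200.0, b: float = 50.0
) -> tuple[float, float, float]:
    """Brown-sector RGB triple with an exact prescribed hue.

    For hue in (0, 60) the red channel is the max and blue the min, so
    hue = 60*(G-B)/(R-B); solving for G gives an RGB triple whose hue is
    exactly ``hue_deg``.  Defaults keep the mean luminance near 0.47 so the
    kernel clears the 0.4 minimum-luminance threshold used in segmentation.
    """
    if not 0.0 < hue_deg < 60.0:
        raise ValueError("body hue must lie in the red-yellow sector (0, 60)")
    g = b + (hue_deg / 60.0) * (r - b)
    return (r, g, b)


@dataclass
class ScanSpec:
    """Parameters for one synthetic kernel scan.

    Defaults emulate a compressed flatbed scan: ~50-80 kernels would sit on
    a full plot image; smaller counts on smaller canvases keep the same
    kernel-scale geometry.  ``body_hues`` fixes each kernel's body hue
    (degrees); if None, hues are drawn uniformly from ``hue_range``.
    """

    height: int = 600
    width: int = 800
    n_kernels: int = 12
    hue_range: tuple[float, float] = (24.0, 42.0)
    body_hues: list[float] | None = None
    length_range: tuple[float, float] = (64.0, 84.0)
    lw_ratio_range: tuple[float, float] = (1.35, 1.75)
    cap_fraction: float = 0.12      # basal band painted cap color
    tip_fraction: float = 0.08      # apical zone painted tip color
    with_cap: bool = True
    with_tip: bool = True
    n_touching_pairs: int = 0
    n_debris: int = 0
    debris_radius: float = 3.0
    damaged_fraction: float = 0.0
    background_rgb: tuple[float, float, float] = (16.0, 15.0, 18.0)
    noise_sd: float = 2.0
    min_gap_px: float = 16.0  # wide enough that cleaning never bridges neighbors
    max_place_tries: int = 2000


def _kernel_mask_local(
    length: float, width: float, angle_deg: float, center: tuple[float, float],
    shape: tuple[int, int], k_tip: float = 1.35, k_base: float = 3.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one ovoid kernel; returns (mask, axial position in [0,1]).

    The outline is a piecewise superellipse: the tip half uses a small
    exponent (pointed) and the base half a large one (blunt), so the two
    ends are geometrically distinguishable.  Axial position is 0 at the tip
    and 1 at the base.
    """
    h, w = shape
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    th = np.deg2rad(angle_deg)
    # axis unit vector points tip -> base
    ax = rows * np.cos(th) + cols * np.sin(th)       # along-axis coordinate
    perp = -rows * np.sin(th) + cols * np.cos(th)    # across-axis coordinate
    a = length / 2.0
    b = width / 2.0
    t = ax / a  # -1 at tip, +1 at base
    k = np.where(t < 0, k_tip, k_base)
    with np.errstate(invalid="ignore"):
        half_w = b * np.power(
            np.clip(1.0 - np.power(np.abs(np.clip(t, -1, 1)), k), 0.0, 1.0), 1.0 / k
        )
    mask = (np.abs(t) <= 1.0) & (np.abs(perp) <= half_w)
    axial = np.clip((t + 1.0) / 2.0, 0.0, 1.0)
    return mask, axial


def _cap_tip_colors(body: tuple[float, float, float]):
    r, g, b = body
    cap = (min(255.0, r * 1.12 + 12), min(255.0, g * 1.25 + 25), b * 0.9)
    tip = (r * 0.55, g * 0.5, b * 0.6)
    return cap, tip


def generate_kernel_scan(
    spec: ScanSpec, seed: int
) -> tuple[np.ndarray, ImageTruth]:
    """Render a synthetic kernel scan and its ground truth.

    Kernels are placed by rejection sampling with a minimum bounding-circle
    gap; requested touching pairs are the only allowed contacts.  Raises
    :class:`PlacementError` when the canvas cannot hold the request.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_rgb
    labels = np.zeros((h, w), dtype=np.int32)

    n = spec.n_kernels
    if spec.body_hues is not None and len(spec.body_hues) != n:
        raise ValueError("body_hues must have one entry per kernel")
    if n == 0:
        noisy = np.clip(img + rng.normal(0, spec.noise_sd, img.shape), 0, 255)
        truth = ImageTruth(0, [], spec.background_rgb, 0, labels, seed)
        return noisy.astype(np.uint8), truth

    lengths = rng.uniform(*spec.length_range, size=n)
    ratios = rng.uniform(*spec.lw_ratio_range, size=n)
    widths = lengths / ratios
    if spec.body_hues is not None:
        hues = np.asarray(spec.body_hues, dtype=float)
    else:
        hues = rng.uniform(*spec.hue_range, size=n)
    angles = rng.uniform(0.0, 360.0, size=n)
    damaged = rng.random(n) < spec.damaged_fraction

    # choose which kernels form touching pairs: (0,1), (2,3), ...
    n_pair_members = 2 * spec.n_touching_pairs
    if n_pair_members > n:
        raise ValueError("more touching-pair members than kernels")

    radii = lengths / 2.0
    margin = radii + 2.0
    centers: list[tuple[float, float]] = []

    def outline_radius(k: int, phi: float) -> float:
        """Exact superellipse outline radius of kernel k in direction phi."""
        th = np.deg2rad(angles[k])
        a, b = lengths[k] / 2.0, widths[k] / 2.0
        co, si = np.cos(phi - th), np.sin(phi - th)
        kk = 1.35 if co < 0 else 3.2  # matches the rendered tip/base halves
        return float(
            ((np.abs(co) / a) ** kk + (np.abs(si) / b) ** kk) ** (-1.0 / kk)
        )

    def place_one(i: int, near: tuple[float, float] | None, touch_with: int | None):
        for _ in range(spec.max_place_tries):
            if near is None:
                c = (
                    rng.uniform(margin[i], h - margin[i]),
                    rng.uniform(margin[i], w - margin[i]),
                )
            else:
                # put the partner so the two outlines just touch/overlap a hair
                phi = rng.uniform(0, 2 * np.pi)
                # outlines in contact: the cleaning stage's closing joins
                # them into one component with a thin neck to be split
                d = 1.02 * (
                    outline_radius(touch_with, phi) + outline_radius(i, phi + np.pi)
                )
                c = (near[0] + d * np.cos(phi), near[1] + d * np.sin(phi))
                if not (margin[i] <= c[0] <= h - margin[i]
                        and margin[i] <= c[1] <= w - margin[i]):
                    continue
            ok = True
            for j, cj in enumerate(centers):
                if touch_with is not None and j == touch_with:
                    continue
                dist = np.hypot(c[0] - cj[0], c[1] - cj[1])
                if dist < radii[i] + radii[j] + spec.min_gap_px:
                    ok = False
                    break
            if ok:
                return c
        raise PlacementError(
            f"could not place kernel {i} after {spec.max_place_tries} tries "
            f"({n} kernels on a {h}x{w} canvas)"
        )

    order = list(range(n))
    for i in order:
        if i < n_pair_members and i % 2 == 1:
            centers.append(place_one(i, centers[i - 1], i - 1))
        else:
            centers.append(place_one(i, None, None))

    per_kernel: list[KernelSpec] = []
    for i in range(n):
        body = body_rgb_for_hue(hues[i])
        cap, tip = _cap_tip_colors(body)
        mask, axial = _kernel_mask_local(
            lengths[i], widths[i], angles[i], centers[i], (h, w)
        )
        cut_face = np.zeros_like(mask)
        if damaged[i]:
            # chipped kernel: a chord cut removes a large chunk and exposes
            # yellow endosperm along the cut face (too big for the cleaning
            # stage to repair, as with real broken kernels)
            psi = rng.uniform(0, 2 * np.pi)
            d_cut = rng.uniform(0.0, 0.35) * lengths[i] / 2.0
            rr = np.arange(h)[:, None] - centers[i][0]
            cc = np.arange(w)[None, :] - centers[i][1]
            proj = rr * np.cos(psi) + cc * np.sin(psi)
            cut_face = mask & (proj > d_cut - 5.0) & (proj <= d_cut)
            mask = mask & (proj <= d_cut)
        img[mask] = body
        if damaged[i]:
            img[cut_face] = (235.0, 215.0, 150.0)  # exposed endosperm
        # cap and tip colors form rounded domes around the two apexes,
        # like the endosperm crown and pedicel scar of a real kernel
        th_i = np.deg2rad(angles[i])
        axis_dir = np.array([np.cos(th_i), np.sin(th_i)])
        rr_all = np.arange(h)[:, None]
        cc_all = np.arange(w)[None, :]
        if spec.with_tip:
            apex = np.asarray(centers[i]) - (lengths[i] / 2.0) * axis_dir
            d2 = (rr_all - apex[0]) ** 2 + (cc_all - apex[1]) ** 2
            img[mask & (d2 < (spec.tip_fraction * lengths[i]) ** 2)] = tip
        if spec.with_cap:
            apex = np.asarray(centers[i]) + (lengths[i] / 2.0) * axis_dir
            d2 = (rr_all - apex[0]) ** 2 + (cc_all - apex[1]) ** 2
            img[mask & (d2 < (spec.cap_fraction * lengths[i]) ** 2)] = cap
        labels[mask] = i + 1
        per_kernel.append(
            KernelSpec(
                center=centers[i],
                angle_deg=float(angles[i]),
                length_px=float(lengths[i]),
                width_px=float(widths[i]),
                body_rgb=body,
                cap_rgb=cap if spec.with_cap else None,
                tip_rgb=tip if spec.with_tip else None,
                damaged=bool(damaged[i]),
            )
        )

    for _ in range(spec.n_debris):
        for _ in range(spec.max_place_tries):
            c = (rng.uniform(5, h - 5), rng.uniform(5, w - 5))
            if all(
                np.hypot(c[0] - cj[0], c[1] - cj[1]) > radii[j] + 8
                for j, cj in enumerate(centers)
            ):
                break
        rr = np.arange(h)[:, None] - c[0]
        cc = np.arange(w)[None, :] - c[1]
        blob = rr * rr + cc * cc <= spec.debris_radius ** 2
        img[blob] = (150.0, 140.0, 120.0)

    noisy = np.clip(img + rng.normal(0, spec.noise_sd, img.shape), 0, 255)
    truth = ImageTruth(
        kernel_count=n,
        per_kernel=per_kernel,
        background_rgb=spec.background_rgb,
        debris_count=spec.n_debris,
        labels=labels,
        seed=seed,
    )
    return noisy.astype(np.uint8), truth


# --------------------------------------------------------------------------
# DH populations
# --------------------------------------------------------------------------

def haldane_cm_to_recfrac(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2 for d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class SimTruth:
    """Ground truth of a simulated DH population's phenotype model."""

    model: GeneticModel
    causal_markers: dict[str, str]          # locus label -> marker name
    qtl: list[tuple[str, float]]            # (marker name, effect in hue deg)
    baseline_hue: float = 34.0
    replicate_sd: float = 0.5
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        for _, eff in self.qtl:
            if not np.isfinite(eff):
                raise ValueError("QTL effects must be finite")


@dataclass
class SimulatedPopulation:
    """A simulated population plus its per-replicate phenotypes and truth."""

    population: DHPopulation
    pheno: pd.DataFrame  # line_id, replicate, hue, pigment_class
    truth: SimTruth
    rep_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))


def default_marker_map(
    n_chrom: int = 3, markers_per_chrom: int = 40, spacing_cm: float = 2.5
) -> pd.DataFrame:
    """Evenly spaced marker map: columns marker, chrom, pos_cm."""
    rows = []
    for c in range(1, n_chrom + 1):
        for m in range(markers_per_chrom):
            rows.append(
                {"marker": f"c{c}m{m + 1}", "chrom": str(c),
                 "pos_cm": m * spacing_cm}
            )
    return pd.DataFrame(rows)


def simulate_dh_population(
    n_individuals: int,
    marker_map: pd.DataFrame,
    truth: SimTruth,
    n_reps: int = 2,
    two_rep_fraction: float = 0.33,
    missing_rate: float = 0.02,
    error_rate: float = 0.002,
    rating_noise_sd: float = 0.3,
    functional_parent: str = "A",
    population_id: str = "simPop",
    parents: tuple[str, str] = ("parentA", "parentB"),
) -> SimulatedPopulation:
    """Simulate a biparental DH population segregating for pericarp pigment.

    Genotypes: per chromosome, each DH is a two-state Markov chain over the
    ordered markers with transition probability given by the Haldane map
    function on the inter-marker distance; the chain start is a fair coin,
    so every marker segregates 1:1 in expectation.  Genotyping errors flip
    calls at ``error_rate`` and missingness blanks them at ``missing_rate``
    (recorded only in the emitted genotype matrix; phenotypes use the true
    genotypes).

    Phenotypes: the qualitative pigment class evaluates ``truth.model`` at
    the causal markers (a locus is "functional" when the line carries
    ``functional_parent``'s allele there).  Quantitative hue per replicate is
    baseline - sum(effects of carried QTL donor alleles) + replicate effect
    + residual, with replicate effects drawn once per replicate.  Lines
    beyond ``two_rep_fraction`` are observed in replicate 1 only, mirroring
    an unbalanced second harvest.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    mm = marker_map.reset_index(drop=True)
    for _, grp in mm.groupby("chrom", sort=False):
        pos = grp["pos_cm"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing "
                             "within each chromosome")
    marker_names = mm["marker"].tolist()
    name_to_col = {m: i for i, m in enumerate(marker_names)}
    for locus, marker in truth.causal_markers.items():
        if marker not in name_to_col:
            raise ValueError(f"causal locus {locus!r} maps to marker "
                             f"{marker!r} which is not on the map")
    for marker, _ in truth.qtl:
        if marker not in name_to_col:
            raise ValueError(f"QTL marker {marker!r} is not on the map")

    rng = np.random.default_rng(truth.seed)
    n_markers = len(mm)
    geno = np.zeros((n_individuals, n_markers), dtype=np.int8)  # 0 = A, 1 = B

    col = 0
    for _, grp in mm.groupby("chrom", sort=False):
        pos = grp["pos_cm"].to_numpy()
        m = len(pos)
        rec = haldane_cm_to_recfrac(np.diff(pos))
        state = rng.integers(0, 2, size=n_individuals).astype(np.int8)
        geno[:, col] = state
        for j in range(1, m):
            flip = rng.random(n_individuals) < rec[j - 1]
            state = np.where(flip, 1 - state, state).astype(np.int8)
            geno[:, col + j] = state
        col += m

    # qualitative pigment class from the true genotypes
    pigment = np.zeros(n_individuals, dtype=int)
    func_code = 0 if functional_parent == "A" else 1
    for i in range(n_individuals):
        genotype = {
            locus: geno[i, name_to_col[marker]] == func_code
            for locus, marker in truth.causal_markers.items()
        }
        pigment[i] = int(truth.model.is_pigmented(genotype))

    # quantitative hue: carrying the donor (functional-parent) allele at a
    # QTL marker lowers hue by that QTL's effect
    genetic_value = np.full(n_individuals, truth.baseline_hue, dtype=float)
    for marker, eff in truth.qtl:
        carries = geno[:, name_to_col[marker]] == func_code
        genetic_value = genetic_value - eff * carries

    # 1-5 visual darkness rating: monotone decreasing in true hue, with a
    # little scorer noise (1 = nonpigmented/light, 5 = dark)
    gv_lo, gv_hi = genetic_value.min(), genetic_value.max()
    span = max(gv_hi - gv_lo, 1e-9)
    rating_raw = 1.0 + 4.0 * (gv_hi - genetic_value) / span
    rating = np.clip(
        np.rint(rating_raw + rng.normal(0.0, rating_noise_sd, n_individuals)),
        1, 5,
    ).astype(int)

    rep_effects = rng.normal(0.0, truth.replicate_sd, size=n_reps)
    n_two = int(round(two_rep_fraction * n_individuals))
    line_ids = [f"{population_id}_{i + 1:04d}" for i in range(n_individuals)]
    rows = []
    for i in range(n_individuals):
        reps = range(n_reps) if i < n_two else [0]
        for r in reps:
            hue = (genetic_value[i] + rep_effects[r]
                   + rng.normal(0.0, truth.residual_sd))
            rows.append(
                {"line_id": line_ids[i], "replicate": r + 1, "hue": hue,
                 "pigment_class": pigment[i], "visual_rating": rating[i]}
            )
    pheno = pd.DataFrame(rows)

    # emitted genotype matrix with injected errors and missingness
    emitted = geno.copy()
    if error_rate > 0:
        flip = rng.random(emitted.shape) < error_rate
        emitted = np.where(flip, 1 - emitted, emitted).astype(np.int8)
    codes = np.where(emitted == 0, "A", "B").astype(object)
    if missing_rate > 0:
        miss = rng.random(emitted.shape) < missing_rate
        codes[miss] = None
    geno_df = pd.DataFrame(codes, index=line_ids, columns=marker_names)

    line_means = pheno.groupby("line_id", sort=False)["hue"].mean()
    population = DHPopulation(
        genotypes=geno_df,
        marker_map=mm,
        phenotypes=line_means.reindex(line_ids),
        population_id=population_id,
        parents=parents,
    )
    return SimulatedPopulation(
        population=population, pheno=pheno, truth=truth, rep_effects=rep_effects
    )
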
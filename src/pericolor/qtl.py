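"""Single-QTL genome scan for biparental doubled-haploid populations.

The scan follows the classical interval-mapping workflow for a two-genotype
(DH) cross: marker/individual quality control, genotype probabilities from
a two-state hidden Markov model along each chromosome, Haley-Knott
regression of the phenotype on P(A) giving a LOD curve, a genome-wide
permutation threshold, Bayes credible intervals around significant peaks,
and a shrunken (BLUP) allele effect at each peak.  Supporting statistics
for association results — pairwise LD r-squared and the adjusted R-squared
of a phenotype-on-dosage regression — live here too.

Positions may be genetic (``pos_cm``) or physical (``pos_mbp``); physical
maps are converted at a configurable cM/Mbp rate (default 1) before any
map-distance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DHPopulation",
    "GenotypeProbabilities",
    "QCReport",
    "ScanResult",
    "Peak",
    "ensure_cm_positions",
    "count_crossovers",
    "filter_markers_individuals",
    "dh_genotype_probabilities",
    "hk_scan",
    "permutation_threshold",
    "peak_intervals",
    "blup_allele_effect",
    "ld_r2",
    "variance_explained",
    "bonferroni_threshold",
]

LOD_CAP = 50.0


@dataclass
class DHPopulation:
    """Genotypes, map and phenotypes for one biparental DH population.

    ``genotypes``: individuals x markers DataFrame with values "A", "B" or
    None/NaN for missing.  ``marker_map``: DataFrame with columns ``marker``,
    ``chrom`` and ``pos_cm`` (or ``pos_mbp``).  ``phenotypes``: per-line
    Series aligned to the genotype index (typically hue BLUEs).
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    phenotypes: pd.Series | None = None
    population_id: str = ""
    parents: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.genotypes.index.has_duplicates:
            raise ValueError("duplicate individual labels")
        if self.genotypes.columns.has_duplicates:
            raise ValueError("duplicate marker labels")
        mm = self.marker_map
        missing = set(self.genotypes.columns) - set(mm["marker"])
        if missing:
            raise ValueError(f"{len(missing)} genotyped markers absent from map")
        for _, grp in mm.groupby("chrom", sort=False):
            pos_col = "pos_cm" if "pos_cm" in mm.columns else "pos_mbp"
            if np.any(np.diff(grp[pos_col].to_numpy()) <= 0):
                raise ValueError(
                    "map positions must be strictly increasing within chromosome"
                )

    def genotype_codes(self) -> np.ndarray:
        """int8 matrix: 0 = allele A, 1 = allele B, -1 = missing."""
        vals = self.genotypes.to_numpy(dtype=object)
        codes = np.full(vals.shape, -1, dtype=np.int8)
        codes[vals == "A"] = 0
        codes[vals == "B"] = 1
        return codes


def ensure_cm_positions(marker_map: pd.DataFrame, cm_per_mbp: float = 1.0) -> pd.DataFrame:
    """Return a map with a ``pos_cm`` column, converting from Mbp if needed."""
    mm = marker_map.copy()
    if "pos_cm" not in mm.columns:
        if "pos_mbp" not in mm.columns:
            raise ValueError("marker map needs pos_cm or pos_mbp")
        mm["pos_cm"] = mm["pos_mbp"] * cm_per_mbp
    return mm


@dataclass
class QCReport:
    """Record of every marker/individual removed during QC."""

    removed_markers: pd.DataFrame
    removed_individuals: pd.DataFrame
    n_markers_kept: int
    n_individuals_kept: int


def count_crossovers(codes: np.ndarray, chrom_slices: list[slice]) -> np.ndarray:
    """Apparent crossovers per individual: allele switches between
    consecutive non-missing calls within each chromosome."""
    n = codes.shape[0]
    total = np.zeros(n, dtype=int)
    for sl in chrom_slices:
        block = codes[:, sl]
        for i in range(n):
            row = block[i][block[i] >= 0]
            if row.size > 1:
                total[i] += int(np.sum(row[1:] != row[:-1]))
    return total


def _chrom_slices(marker_map: pd.DataFrame) -> list[slice]:
    slices = []
    start = 0
    for _, grp in marker_map.groupby("chrom", sort=False):
        slices.append(slice(start, start + len(grp)))
        start += len(grp)
    return slices


def filter_markers_individuals(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    max_marker_missing: float = 0.75,
    min_maf: float = 0.05,
    max_crossovers: int = 200,
    max_individual_missing: float = 0.15,
    population_id: str = "",
    parents: tuple[str, str] = ("A", "B"),
) -> tuple[DHPopulation, QCReport]:
    """Standard DH QC: drop bad markers first, then bad individuals.

    Markers fail on missingness > ``max_marker_missing``, minor allele
    frequency < ``min_maf``, or monomorphism.  Individuals then fail on more
    than ``max_crossovers`` apparent crossovers (computed on the ordered,
    QC-passing markers) or missingness > ``max_individual_missing``.
    """
    order = [m for m in marker_map["marker"] if m in set(genotypes.columns)]
    geno = genotypes[order]
    mm = marker_map[marker_map["marker"].isin(order)].reset_index(drop=True)

    vals = geno.to_numpy(dtype=object)
    is_a = vals == "A"
    is_b = vals == "B"
    typed = is_a | is_b
    n_ind = len(geno)

    miss_frac = 1.0 - typed.sum(axis=0) / n_ind
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq_b = np.where(n_typed > 0, is_b.sum(axis=0) / np.maximum(n_typed, 1), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)

    marker_rows = []
    keep_marker = np.ones(len(order), dtype=bool)
    for j, m in enumerate(order):
        if miss_frac[j] > max_marker_missing:
            marker_rows.append({"marker": m, "reason": "missingness",
                                "value": miss_frac[j]})
            keep_marker[j] = False
        elif n_typed[j] == 0 or np.isnan(maf[j]) or maf[j] == 0.0:
            marker_rows.append({"marker": m, "reason": "monomorphic",
                                "value": 0.0})
            keep_marker[j] = False
        elif maf[j] < min_maf:
            marker_rows.append({"marker": m, "reason": "maf", "value": maf[j]})
            keep_marker[j] = False
    kept_markers = [m for j, m in enumerate(order) if keep_marker[j]]
    if not kept_markers:
        raise ValueError("all markers removed by QC")
    geno = geno[kept_markers]
    mm = mm[mm["marker"].isin(kept_markers)].reset_index(drop=True)

    pop = DHPopulation(geno, mm, population_id=population_id, parents=parents)
    codes = pop.genotype_codes()
    xo = count_crossovers(codes, _chrom_slices(mm))
    ind_miss = (codes == -1).sum(axis=1) / codes.shape[1]

    ind_rows = []
    keep_ind = np.ones(len(geno), dtype=bool)
    for i, ind in enumerate(geno.index):
        reasons = []
        if xo[i] > max_crossovers:
            reasons.append(("crossovers", float(xo[i])))
        if ind_miss[i] > max_individual_missing:
            reasons.append(("missingness", float(ind_miss[i])))
        if reasons:
            keep_ind[i] = False
            for reason, value in reasons:
                ind_rows.append({"individual": ind, "reason": reason,
                                 "value": value})
    geno = geno[keep_ind]

    report = QCReport(
        removed_markers=pd.DataFrame(marker_rows,
                                     columns=["marker", "reason", "value"]),
        removed_individuals=pd.DataFrame(ind_rows,
                                         columns=["individual", "reason", "value"]),
        n_markers_kept=len(kept_markers),
        n_individuals_kept=int(keep_ind.sum()),
    )
    return (
        DHPopulation(geno, mm, population_id=population_id, parents=parents),
        report,
    )


@dataclass
class GenotypeProbabilities:
    """Posterior P(allele A) per individual x marker from the HMM."""

    p_a: np.ndarray              # n_individuals x n_markers
    marker_map: pd.DataFrame
    individuals: pd.Index
    parents: tuple[str, str] = ("A", "B")

    @property
    def p_b(self) -> np.ndarray:
        return 1.0 - self.p_a

    def __post_init__(self) -> None:
        if np.any(self.p_a < -1e-9) or np.any(self.p_a > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")


def _haldane(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def dh_genotype_probabilities(
    population: DHPopulation,
    error_rate: float = 0.002,
    cm_per_mbp: float = 1.0,
) -> GenotypeProbabilities:
    """Two-state forward-backward HMM posteriors per chromosome.

    Hidden state is the parental origin at each marker; transitions between
    adjacent markers use the Haldane recombination fraction of the map
    distance; emissions allow a symmetric genotyping-error rate; missing
    calls emit uninformatively.  A uniform prior (1/2, 1/2) matches the DH
    cross.  All individuals are processed vectorized per chromosome.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    mm = ensure_cm_positions(population.marker_map, cm_per_mbp)
    codes = population.genotype_codes()
    n, n_markers = codes.shape
    p_a = np.empty((n, n_markers), dtype=float)

    for sl, (_, grp) in zip(_chrom_slices(mm), mm.groupby("chrom", sort=False)):
        m = sl.stop - sl.start
        if m == 0:
            warnings.warn(f"chromosome {grp['chrom'].iloc[0]} has no markers; skipped")
            continue
        obs = codes[:, sl]
        rec = _haldane(np.diff(grp["pos_cm"].to_numpy()))

        # emission likelihoods e[i, j, s] for state s in {A, B}
        e = np.ones((n, m, 2), dtype=float)
        typed = obs >= 0
        e[..., 0] = np.where(typed, np.where(obs == 0, 1 - error_rate, error_rate), 1.0)
        e[..., 1] = np.where(typed, np.where(obs == 1, 1 - error_rate, error_rate), 1.0)

        fwd = np.empty((n, m, 2), dtype=float)
        f = 0.5 * e[:, 0, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, 0, :] = f
        for j in range(1, m):
            r = rec[j - 1]
            trans = np.array([[1 - r, r], [r, 1 - r]])
            f = (f @ trans) * e[:, j, :]
            f /= f.sum(axis=1, keepdims=True)
            fwd[:, j, :] = f

        b = np.ones((n, 2), dtype=float)
        post = np.empty((n, m, 2), dtype=float)
        post[:, m - 1, :] = fwd[:, m - 1, :]
        for j in range(m - 2, -1, -1):
            r = rec[j]
            trans = np.array([[1 - r, r], [r, 1 - r]])
            b = (b * e[:, j + 1, :]) @ trans.T
            b /= b.sum(axis=1, keepdims=True)
            pj = fwd[:, j, :] * b
            pj /= pj.sum(axis=1, keepdims=True)
            post[:, j, :] = pj
        p_a[:, sl] = post[..., 0]

    return GenotypeProbabilities(
        p_a=p_a, marker_map=mm, individuals=population.genotypes.index,
        parents=population.parents,
    )


def _aligned_phenotype(
    probs: GenotypeProbabilities, phenotypes: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    pheno = phenotypes.reindex(probs.individuals)
    ok = pheno.notna().to_numpy()
    return probs.p_a[ok], pheno.to_numpy(dtype=float)[ok]


def _lod_from_corr_sq(r2: np.ndarray, n: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(1.0 - r2)
    return np.minimum(lod, LOD_CAP)


def hk_scan(probs: GenotypeProbabilities, phenotypes: pd.Series) -> pd.DataFrame:
    """Haley-Knott regression LOD at every marker.

    Regressing the phenotype on P(A) at a single position gives
    LOD = -(n/2) log10(1 - r^2) with r the phenotype-P(A) correlation;
    monomorphic positions score 0 and numerically perfect fits are capped
    at LOD 50 and flagged.
    """
    G, y = _aligned_phenotype(probs, phenotypes)
    n = len(y)
    if n < 20:
        raise ValueError(f"phenotype available for only {n} individuals (< 20)")
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    Gc = G - G.mean(axis=0)
    gnorm = np.linalg.norm(Gc, axis=0)
    r2 = np.zeros(G.shape[1])
    ok = (gnorm > 1e-12) & (ynorm > 1e-12)
    r2[ok] = (yc @ Gc[:, ok] / (ynorm * gnorm[ok])) ** 2
    lod = _lod_from_corr_sq(r2, n)
    out = probs.marker_map.copy()
    out["lod"] = lod
    out["lod_capped"] = lod >= LOD_CAP
    return out


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotypes: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> tuple[float, np.ndarray]:
    """Genome-wide (1 - alpha) quantile of the max LOD over permutations.

    Phenotype labels are permuted against the genotype probabilities; the
    whole permutation batch is evaluated with one matrix product.  Returns
    (threshold, per-permutation max LODs).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: quantile is unstable")
    G, y = _aligned_phenotype(probs, phenotypes)
    n = len(y)
    rng = np.random.default_rng(seed)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm <= 1e-12:  # constant phenotype: every permuted scan is flat
        return 0.0, np.zeros(n_perm)
    Y = np.empty((n, n_perm))
    for k in range(n_perm):
        Y[:, k] = rng.permutation(yc)
    Gc = G - G.mean(axis=0)
    gnorm = np.linalg.norm(Gc, axis=0)
    ok = gnorm > 1e-12
    R = (Y.T @ Gc[:, ok]) / (ynorm * gnorm[ok])
    max_lod = _lod_from_corr_sq((R ** 2).max(axis=1), n)
    return float(np.quantile(max_lod, 1.0 - alpha)), max_lod


@dataclass
class Peak:
    """One significant QTL peak with its support interval."""

    chrom: str
    marker: str
    pos_cm: float
    lod: float
    interval_lo: float
    interval_hi: float
    allele_effect: float = np.nan
    donor_parent: str = ""


@dataclass
class ScanResult:
    """A completed genome scan: LOD curve, threshold and peaks."""

    lod_table: pd.DataFrame
    threshold: float
    n_perm: int
    peaks: list[Peak] = field(default_factory=list)


def _bayes_interval(pos: np.ndarray, lod: np.ndarray, peak_idx: int,
                    prob: float) -> tuple[float, float]:
    """Smallest contiguous run around the peak holding ``prob`` of the
    normalized 10^LOD mass on the chromosome."""
    w = np.power(10.0, lod - lod.max())
    w /= w.sum()
    lo = hi = peak_idx
    mass = w[peak_idx]
    while mass < prob and (lo > 0 or hi < len(w) - 1):
        left = w[lo - 1] if lo > 0 else -np.inf
        right = w[hi + 1] if hi < len(w) - 1 else -np.inf
        if left >= right:
            lo -= 1
            mass += w[lo]
        else:
            hi += 1
            mass += w[hi]
    return float(pos[lo]), float(pos[hi])


def _lod_drop_interval(pos: np.ndarray, lod: np.ndarray, peak_idx: int,
                       drop: float) -> tuple[float, float]:
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= lod[peak_idx] - drop:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= lod[peak_idx] - drop:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def peak_intervals(
    lod_table: pd.DataFrame,
    threshold: float,
    method: str = "bayes",
    prob: float = 0.95,
    drop: float = 1.5,
) -> list[Peak]:
    """One peak per chromosome whose maximum LOD clears the threshold.

    ``method`` is "bayes" (default: 95% credible interval from the
    normalized 10^LOD mass) or "lod_drop" (contiguous region within
    ``drop`` LOD of the peak).  Ties at the maximum go to the lowest map
    index.  No peaks is a valid outcome.
    """
    peaks: list[Peak] = []
    for _, grp in lod_table.groupby("chrom", sort=False):
        lod = grp["lod"].to_numpy()
        pos = grp["pos_cm"].to_numpy()
        idx = int(np.argmax(lod))
        if lod[idx] < threshold:
            continue
        if method == "bayes":
            lo, hi = _bayes_interval(pos, lod, idx, prob)
        elif method == "lod_drop":
            lo, hi = _lod_drop_interval(pos, lod, idx, drop)
        else:
            raise ValueError(f"unknown interval method {method!r}")
        peaks.append(
            Peak(
                chrom=str(grp["chrom"].iloc[0]),
                marker=str(grp["marker"].iloc[idx]),
                pos_cm=float(pos[idx]),
                lod=float(lod[idx]),
                interval_lo=lo,
                interval_hi=hi,
            )
        )
    return peaks


def blup_allele_effect(
    p_a_at_peak: np.ndarray,
    phenotypes: np.ndarray,
    parents: tuple[str, str] = ("A", "B"),
) -> tuple[float, str]:
    """Shrunken allele-substitution effect at a peak, plus the donor parent.

    The genotype effect is treated as a random coefficient: for centered
    x = P(A) and phenotype y, REML estimates the variance ratio
    lambda = sigma_gamma^2 / sigma_e^2 and the BLUP is

        gamma_hat = lambda x'y / (1 + lambda x'x),

    which shrinks the OLS slope by lambda*S/(1 + lambda*S).  The effect is
    the full A-versus-B contrast in hue degrees; a negative value means the
    first parent's allele lowers hue (darker pericarp), and the donor
    parent is the one whose allele carries the negative effect.
    """
    x = np.asarray(p_a_at_peak, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    S = xc @ xc
    if S <= 1e-12:
        return 0.0, ""
    sxy = xc @ yc

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        shrink = lam / (1.0 + lam * S)
        rss = yc @ yc - shrink * sxy ** 2
        sigma_e2 = max(rss / (n - 1), 1e-12)
        return (n - 1) * np.log(sigma_e2) + np.log1p(lam * S)

    res = minimize_scalar(neg_reml, bounds=(-20.0, 20.0), method="bounded")
    lam = float(np.exp(res.x))
    gamma = lam * sxy / (1.0 + lam * S)
    donor = parents[0] if gamma < 0 else parents[1]
    return float(gamma), donor


def ld_r2(dosages: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between marker dosage vectors.

    Missing values are handled pairwise-complete; monomorphic markers give
    NaN entries (undefined correlation).  The result is symmetric with a
    unit diagonal for polymorphic markers.
    """
    df = pd.DataFrame(dosages)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    return df.corr(method="pearson") ** 2


def variance_explained(blues: np.ndarray, dosage: np.ndarray) -> float:
    """Adjusted R-squared of the simple regression of BLUEs on allele dosage.

    Returns NaN for constant dosage (undefined).  Slightly negative values
    are possible and meaningful under the null.
    """
    y = np.asarray(blues, dtype=float)
    x = np.asarray(dosage, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sx = x.std()
    if sx <= 1e-12:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests
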
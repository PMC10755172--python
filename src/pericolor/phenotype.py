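"""Line BLUEs, Cullis heritability, Tukey groups, visual-rating validation.

The observation model for line-by-replicate hue is

    y_ij = g_i + r_j + e_ij,

with the line effect g_i fixed (BLUEs), the replicate effect r_j random
with variance sigma_rep^2, and iid residuals with variance sigma_e^2.
Restricted maximum likelihood handles the unbalanced case where many lines
appear in only one replicate.  Generalized (Cullis) heritability uses the
companion model with the line effect random to estimate the line variance
sigma_g^2:

    h^2 = 1 - PEV / (2 sigma_g^2),    PEV = avsed^2,

where avsed is the average standard error of a pairwise difference between
predicted line means.  Both REML fits exploit the low-rank structure of
the design (diagonal-plus-few-columns), so ~1,300 lines fit in well under
a second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "BLUESet",
    "HeritabilityEstimate",
    "fit_line_blues",
    "estimate_line_variance",
    "cullis_h2",
    "tukey_groups",
    "spearman_validation",
]


@dataclass
class BLUESet:
    """Per-line BLUEs with their uncertainty and variance components."""

    blues: pd.DataFrame          # line_id, blue, se
    sigma_g2: float              # line variance (random-line companion fit)
    sigma_rep2: float
    sigma_e2: float
    avsed: float                 # mean over pairs of SE(blue_i - blue_j)
    n_lines: int
    n_obs: int
    degenerate: bool = False     # single replicate: plain fixed-effects means
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Cullis generalized heritability."""

    h2: float
    pev: float
    sigma_g2: float


def _design(records: pd.DataFrame):
    lines = pd.Categorical(records["line_id"])
    reps = pd.Categorical(records["replicate"])
    return (
        records["hue"].to_numpy(dtype=float),
        lines.codes.astype(int), list(lines.categories),
        reps.codes.astype(int), len(reps.categories),
    )


def fit_line_blues(records: pd.DataFrame) -> BLUESet:
    """REML fit of fixed line effects with a random replicate effect.

    ``records`` needs columns ``line_id``, ``replicate``, ``hue``.  Returns
    BLUEs (generalized least squares at the REML variance ratio), their
    standard errors, variance components and avsed.  With a single
    replicate level the model degenerates to per-line means (flagged); the
    residual variance then comes from within-line spread where available.

    The replicate variance ratio lambda = sigma_rep^2 / sigma_e^2 is
    profiled by Woodbury identities: with X the line-indicator matrix and
    Z the replicate indicators, X' W^-1 X is a rank-r update of a diagonal
    matrix, so each REML evaluation is O(n + p r^2).
    """
    y, line_codes, line_ids, rep_codes, n_reps = _design(records)
    n = len(y)
    p = len(line_ids)
    if p < 2:
        raise ValueError("need at least 2 lines")
    notes: list[str] = []

    # X'y, counts, X'Z occupancy
    c_line = np.bincount(line_codes, minlength=p).astype(float)
    xty = np.bincount(line_codes, weights=y, minlength=p)
    n_rep = np.bincount(rep_codes, minlength=n_reps).astype(float)
    zty = np.bincount(rep_codes, weights=y, minlength=n_reps)
    A = np.zeros((p, n_reps))
    np.add.at(A, (line_codes, rep_codes), 1.0)

    def gls_pieces(lam: float):
        """Return (ghat, C, y'Py, logdetW, logdet(X'W^-1X)) at ratio lam."""
        M = np.diag(1.0 / max(lam, 1e-12) + n_rep)
        Minv = np.linalg.inv(M)
        XtWX_diag = c_line
        # X'W^-1 X = D - A Minv A'  (rank-r update);  C by Woodbury
        Dinv = 1.0 / XtWX_diag
        inner = M - (A.T * Dinv) @ A
        inner_inv = np.linalg.inv(inner)
        DA = Dinv[:, None] * A
        C = np.diag(Dinv) + DA @ inner_inv @ DA.T
        xtwy = xty - A @ (Minv @ zty)
        ghat = C @ xtwy
        ytwy = y @ y - zty @ Minv @ zty
        ypy = max(ytwy - xtwy @ ghat, 0.0)
        sign1, ld_inner = np.linalg.slogdet(inner)
        sign2, ld_M = np.linalg.slogdet(M)
        logdet_xtwx = np.sum(np.log(XtWX_diag)) + ld_inner - ld_M
        logdet_W = np.sum(np.log1p(lam * n_rep))
        return ghat, C, ypy, logdet_W, logdet_xtwx

    degenerate = n_reps < 2
    if degenerate:
        notes.append("single replicate level: fixed-effects means, "
                     "replicate variance not estimable")
        lam_hat = 0.0
    else:
        def neg_reml(log_lam: float) -> float:
            lam = float(np.exp(log_lam))
            _, _, ypy, ldW, ldX = gls_pieces(lam)
            sigma_e2 = max(ypy / max(n - p, 1), 1e-300)
            return (n - p) * np.log(sigma_e2) + ldW + ldX

        res = minimize_scalar(neg_reml, bounds=(-25.0, 15.0), method="bounded")
        lam_hat = float(np.exp(res.x))

    ghat, C, ypy, _, _ = gls_pieces(lam_hat)
    df_resid = max(n - p, 0)
    sigma_e2 = ypy / df_resid if df_resid > 0 else 0.0
    if df_resid == 0:
        notes.append("no residual degrees of freedom: sigma_e2 set to 0")
    sigma_rep2 = lam_hat * sigma_e2

    var_g = sigma_e2 * C
    se = np.sqrt(np.clip(np.diag(var_g), 0.0, None))
    # avsed: mean over all pairs of sqrt(var(g_i - g_j))
    d = np.diag(var_g)
    sed2 = d[:, None] + d[None, :] - 2.0 * var_g
    iu = np.triu_indices(p, k=1)
    avsed = float(np.sqrt(np.clip(sed2[iu], 0.0, None)).mean())

    sigma_g2, extra = estimate_line_variance(records)
    notes.extend(extra)

    blues = pd.DataFrame({"line_id": line_ids, "blue": ghat, "se": se})
    return BLUESet(
        blues=blues,
        sigma_g2=sigma_g2,
        sigma_rep2=sigma_rep2,
        sigma_e2=sigma_e2,
        avsed=avsed,
        n_lines=p,
        n_obs=n,
        degenerate=degenerate,
        notes=notes,
    )


def estimate_line_variance(records: pd.DataFrame) -> tuple[float, list[str]]:
    """REML line variance from the companion random-line model.

    Fits y = mu + g + r + e with both the line and replicate effects
    random.  Only variance ratios are optimized (Nelder-Mead on the log
    ratios); all linear algebra reduces to a diagonal block plus an
    r x r Schur complement, so the fit is fast at any number of lines.
    """
    y, line_codes, line_ids, rep_codes, n_reps = _design(records)
    n = len(y)
    p = len(line_ids)
    notes: list[str] = []

    c_line = np.bincount(line_codes, minlength=p).astype(float)
    n_rep = np.bincount(rep_codes, minlength=n_reps).astype(float)
    xty = np.bincount(line_codes, weights=y, minlength=p)
    zty = np.bincount(rep_codes, weights=y, minlength=n_reps)
    xt1 = c_line
    zt1 = n_rep
    A = np.zeros((p, n_reps))
    np.add.at(A, (line_codes, rep_codes), 1.0)

    def w_inv_quad(lam_g: float, lam_r: float):
        """(1'W^-1 1, 1'W^-1 y, y'W^-1 y, log|W|) via block elimination."""
        D1 = 1.0 + lam_g * c_line                       # p-vector
        G_scale = np.sqrt(lam_g * lam_r)
        S = np.diag(1.0 + lam_r * n_rep) - (
            G_scale ** 2 * (A.T * (1.0 / D1)) @ A
        )
        S_inv = np.linalg.inv(S)
        logdetW = float(np.sum(np.log(D1)) + np.linalg.slogdet(S)[1])

        def quad(av: np.ndarray, bv: np.ndarray, aw: np.ndarray, bw: np.ndarray,
                 raw: float) -> float:
            # raw - [sqrt(lg) a; sqrt(lr) b]' K^-1 [sqrt(lg) aw; sqrt(lr) bw]
            ra = np.sqrt(lam_g) * av
            rb = np.sqrt(lam_r) * bv
            sa = np.sqrt(lam_g) * aw
            sb = np.sqrt(lam_r) * bw
            zb = S_inv @ (sb - G_scale * (A.T @ (sa / D1)))
            za = (sa - G_scale * (A @ zb)) / D1
            return raw - (ra @ za + rb @ zb)

        q11 = quad(xt1, zt1, xt1, zt1, float(n))
        q1y = quad(xt1, zt1, xty, zty, float(y.sum()))
        qyy = quad(xty, zty, xty, zty, float(y @ y))
        return q11, q1y, qyy, logdetW

    def neg_reml(params: np.ndarray) -> float:
        lam_g, lam_r = np.exp(np.clip(params, -25.0, 15.0))
        q11, q1y, qyy, logdetW = w_inv_quad(lam_g, lam_r)
        ypy = max(qyy - q1y ** 2 / q11, 1e-300)
        sigma_e2 = ypy / (n - 1)
        return (n - 1) * np.log(sigma_e2) + logdetW + np.log(q11)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(neg_reml, x0=np.log([1.0, 0.5]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
    lam_g, lam_r = np.exp(np.clip(res.x, -25.0, 15.0))
    q11, q1y, qyy, _ = w_inv_quad(lam_g, lam_r)
    ypy = max(qyy - q1y ** 2 / q11, 0.0)
    sigma_e2 = ypy / (n - 1)
    sigma_g2 = float(lam_g * sigma_e2)
    if lam_g <= np.exp(-24.0):
        notes.append("line variance hit the zero boundary")
    return sigma_g2, notes


def cullis_h2(sigma_g2: float, avsed: float) -> HeritabilityEstimate:
    """Generalized heritability h^2 = 1 - avsed^2 / (2 sigma_g2)."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive for Cullis heritability")
    if avsed < 0:
        raise ValueError("avsed must be nonnegative")
    pev = avsed ** 2
    return HeritabilityEstimate(h2=1.0 - pev / (2.0 * sigma_g2), pev=pev,
                                sigma_g2=sigma_g2)


def tukey_groups(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> tuple[dict[str, str], pd.DataFrame]:
    """All-pairwise Tukey HSD with a compact letter display.

    Groups sharing no letter differ significantly at family-wise level
    ``alpha`` under the studentized-range distribution.  Groups with a
    single member are excluded with a warning.  Returns
    (letters_by_group, pairwise_table).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "label": np.asarray(labels).astype(str)})
    sizes = df.groupby("label").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups excluded (size 1): {singletons}")
        df = df[~df["label"].isin(singletons)]
    groups = sorted(df["label"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups of size >= 2")

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(df["value"], df["label"], alpha=alpha)
    table = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    table["reject"] = table["reject"].astype(bool)

    means = df.groupby("label")["value"].mean().loc[groups]
    order = means.sort_values().index.tolist()
    differs = {g: set() for g in groups}
    for _, row in table.iterrows():
        if row["reject"]:
            differs[str(row["group1"])].add(str(row["group2"]))
            differs[str(row["group2"])].add(str(row["group1"]))

    # insert-and-absorb compact letter display over mean-ordered groups
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(other not in differs[g] for other in s):
                s.add(g)
                placed = True
        if not placed:
            new = {g} | {
                other for other in order
                if other not in differs[g]
                and all(o2 not in differs[other] for o2 in [g])
                and any(other in s for s in letter_sets)
            }
            # keep only mutually compatible members
            new = {m for m in new
                   if all(o not in differs[m] for o in new if o != m)}
            letter_sets.append(new)
    # drop sets fully contained in another (absorption)
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(i != j and s <= t
                              for j, t in enumerate(letter_sets))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for li, s in enumerate(letter_sets):
        for g in order:
            if g in s:
                letters[g] += alphabet[li % len(alphabet)]
    return letters, table


def spearman_validation(
    hue: np.ndarray, visual_rating: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of hue against 1-5 darkness ratings.

    Midranks handle ties.  Darker pericarp means lower hue and a higher
    rating, so the expected sign is negative.  Constant ratings leave the
    correlation undefined and raise.
    """
    hue = np.asarray(hue, dtype=float)
    rating = np.asarray(visual_rating, dtype=float)
    if len(hue) != len(rating) or len(hue) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(rating == rating[0]) or np.all(hue == hue[0]):
        raise ValueError("correlation undefined for constant input")
    rho, pval = stats.spearmanr(hue, rating)
    return float(rho), float(pval)
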
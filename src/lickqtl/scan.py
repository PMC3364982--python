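"""Genome scans on strain means: LRS/LOD, permutation thresholds,
bootstrap and LOD-drop intervals, composite mapping, and two-locus models.

The mapping unit is the strain mean (one value per strain, unweighted).
At each locus the strain means are regressed on the numeric genotype
(B/B = -1, D/D = +1; expected dosage at pseudomarkers in interval mode)
and linkage is expressed as the likelihood ratio statistic

    LRS = n * ln(RSS0 / RSS1),

comparing the null (mean-only) and single-locus regressions over the n
strains informative at that locus; LOD = LRS / (2 ln 10).  The additive
effect is the regression slope, i.e. half the D/D - B/B group-mean
difference, so a positive value means the D allele raises the trait.

Genome-wide thresholds come from permuting strain phenotype values against
genotype rows and recording each permutation's maximum LRS; the
significant and suggestive thresholds are the empirical quantiles at
genome-wide p = 0.05 and p = 0.63.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenoMap, GenotypeMatrix, ri_transition_probability

logger = logging.getLogger(__name__)

TWO_LN10 = 2.0 * np.log(10.0)

#: relative RSS floor for perfect fits: LRS capped at n*ln(1/LRS_EPS)
LRS_EPS = 1e-12

P_SIGNIFICANT = 0.05
P_SUGGESTIVE = 0.63


def lrs_to_lod(lrs: float | np.ndarray) -> float | np.ndarray:
    """LOD = LRS / (2 ln 10)."""
    arr = np.asarray(lrs, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LRS must be non-negative")
    out = arr / TWO_LN10
    return out if out.ndim else float(out)


@dataclass
class ScanResult:
    """Per-locus scan table plus optional attached thresholds.

    ``table`` columns: locus, chrom, cM, Mb, n, LRS, LOD, additive_effect,
    flag.  Degenerate loci (single genotype class) have NaN LRS and the
    flag ``degenerate``.
    """

    table: pd.DataFrame
    mode: str = "marker"
    threshold_significant: float | None = None
    threshold_suggestive: float | None = None

    def peak(self) -> pd.Series:
        """Row of the genome-wide maximum LRS (leftmost on ties)."""
        lrs = self.table["LRS"].to_numpy()
        if np.all(np.isnan(lrs)):
            raise ValueError("scan has no informative locus")
        idx = int(np.nanargmax(lrs))
        n_ties = int(np.sum(lrs == lrs[idx]))
        if n_ties > 1:
            logger.info("peak tie among %d loci; reporting leftmost", n_ties)
        return self.table.iloc[idx]

    @property
    def max_lrs(self) -> float:
        return float(np.nanmax(self.table["LRS"].to_numpy()))


@dataclass(frozen=True)
class QTLInterval:
    """LOD-drop support interval around a scan peak (one chromosome)."""

    chrom: str
    peak_locus: str
    left_cM: float
    right_cM: float
    left_Mb: float
    right_Mb: float
    drop: float


@dataclass(frozen=True)
class PermutationThresholds:
    """Empirical genome-wide LRS thresholds from a permutation null."""

    significant: float  # genome-wide p = 0.05
    suggestive: float  # genome-wide p = 0.63
    null_max_lrs: np.ndarray
    n_perm: int
    seed: int


@dataclass
class TwoQTLFit:
    """Joint fit of two loci with an optional epistatic product term.

    The full model is y = mu + a1*x1 + a2*x2 + i*x1*x2; ``interaction_LRS``
    compares it with the additive model, and ``variance_explained`` gives
    each locus's sequential share of the between-strain sum of squares
    after the other locus.
    """

    marker1: str
    marker2: str
    n: int
    total_LRS: float
    additive_LRS: dict[str, float]
    interaction_LRS: float
    coefficients: dict[str, float]  # intercept, a1, a2, i
    variance_explained: dict[str, float]
    interaction_dropped: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignment and core regression helpers

def _align(pheno, geno: GenotypeMatrix, min_strains: int = 8):
    """Common strains with a defined phenotype, in genotype order."""
    s = pd.Series(pheno).astype(float)
    keep = [i for i, name in enumerate(geno.strains)
            if name in s.index and np.isfinite(s[name])]
    if len(keep) < min_strains:
        raise ValueError(
            f"need >= {min_strains} strains with phenotype and genotype, "
            f"have {len(keep)}")
    y = s[[geno.strains[i] for i in keep]].to_numpy(dtype=float)
    return np.asarray(keep), y


def _cap_lrs(n: int) -> float:
    return float(n * np.log(1.0 / LRS_EPS))


def _scan_columns(y: np.ndarray, D: np.ndarray):
    """LRS/slope/n for every dosage column (NaN-aware per column).

    Returns (n_used, lrs, slope, flags) arrays; degenerate columns get
    NaN LRS, perfect fits are capped at n*ln(1/LRS_EPS).
    """
    n_rows, m = D.shape
    n_used = np.empty(m, dtype=int)
    lrs = np.full(m, np.nan)
    slope = np.full(m, np.nan)
    flags = np.full(m, "", dtype=object)

    col_has_nan = np.isnan(D).any(axis=0)
    clean = ~col_has_nan
    if clean.any():
        n_used[clean], lrs[clean], slope[clean], fl = _scan_dense(y, D[:, clean])
        flags[clean] = fl
    for j in np.flatnonzero(col_has_nan):
        mask = ~np.isnan(D[:, j])
        nj = int(mask.sum())
        n_used[j] = nj
        if nj < 3:
            flags[j] = "degenerate"
            continue
        _, l, s, f = _scan_dense(y[mask], D[mask, j][:, None])
        lrs[j], slope[j], flags[j] = l[0], s[0], f[0]
    return n_used, lrs, slope, flags


def _scan_dense(y: np.ndarray, D: np.ndarray):
    """Vectorized single-locus regression over complete dosage columns."""
    n, m = D.shape
    yc = y - y.mean()
    ss0 = float(yc @ yc)
    n_used = np.full(m, n)
    flags = np.full(m, "", dtype=object)
    Dc = D - D.mean(axis=0)
    sx = np.einsum("ij,ij->j", Dc, Dc)
    degenerate = sx <= 1e-12
    flags[degenerate] = "degenerate"
    if ss0 <= 0.0:  # constant phenotype: no linkage anywhere
        lrs = np.where(degenerate, np.nan, 0.0)
        return n_used, lrs, np.zeros(m), flags
    sxy = Dc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sx
        r2 = sxy**2 / (sx * ss0)
    lrs = np.full(m, np.nan)
    ok = ~degenerate
    frac = np.clip(1.0 - r2[ok], LRS_EPS, None)
    lrs[ok] = -n * np.log(frac)
    perfect = ok.copy()
    perfect[ok] = r2[ok] >= 1.0 - LRS_EPS
    flags[perfect] = "perfect_fit"
    slope[degenerate] = np.nan
    return n_used, lrs, slope, flags


# ---------------------------------------------------------------------------
# dosage construction

def marker_dosage(geno: GenotypeMatrix, rows: np.ndarray):
    """Observed dosage matrix for a strain subset, with marker info table."""
    D = geno.dosage()[rows]
    info = geno.gmap.table.rename(columns={"name": "locus"}).copy()
    info["is_marker"] = True
    return info.reset_index(drop=True), D


def interval_dosage(geno: GenotypeMatrix, rows: np.ndarray, grid_cM: float = 1.0):
    """Expected dosage on a cM grid plus the observed markers.

    At a pseudomarker between flanking markers the conditional expectation
    E[x | flanks] uses the RI-expanded Markov transitions (Haldane r,
    R = 4r/(1+6r)); a missing flank contributes a flat 1/2 prior.
    Physical positions are interpolated linearly between flanking markers.
    """
    X = geno.dosage()[rows]
    t = geno.gmap.table
    info_rows, cols = [], []
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["cM"].to_numpy(dtype=float)
        mb = grp["Mb"].to_numpy(dtype=float)
        grid = np.unique(np.concatenate(
            [cm, np.arange(cm[0], cm[-1] + 1e-9, grid_cM)]))
        for p in grid:
            j = int(np.searchsorted(cm, p, side="right")) - 1
            if j >= 0 and np.isclose(cm[j], p):  # an actual marker
                info_rows.append((grp.iloc[j]["name"], chrom, cm[j], mb[j], True))
                cols.append(X[:, idx[j]])
                continue
            xa, xb = X[:, idx[j]], X[:, idx[j + 1]]
            R1 = ri_transition_probability(p - cm[j])
            R2 = ri_transition_probability(cm[j + 1] - p)
            pa = np.where(np.isnan(xa), 0.5, (1.0 + xa * (1.0 - 2.0 * R1)) / 2.0)
            pb = np.where(np.isnan(xb), 0.5, (1.0 + xb * (1.0 - 2.0 * R2)) / 2.0)
            w_plus = pa * pb
            w_minus = (1.0 - pa) * (1.0 - pb)
            ex = (w_plus - w_minus) / (w_plus + w_minus)
            frac = (p - cm[j]) / (cm[j + 1] - cm[j])
            info_rows.append((f"c{chrom}@{p:.1f}", chrom, p,
                              mb[j] + frac * (mb[j + 1] - mb[j]), False))
            cols.append(ex)
    info = pd.DataFrame(info_rows, columns=["locus", "chrom", "cM", "Mb", "is_marker"])
    return info, np.column_stack(cols)


# ---------------------------------------------------------------------------
# public operations

def scan_single(
    pheno, geno: GenotypeMatrix, mode: str = "marker", grid_cM: float = 1.0,
    min_strains: int = 8,
) -> ScanResult:
    """Single-locus genome scan of strain means.

    ``pheno`` maps strain name -> trait value (Series or dict).  In
    ``interval`` mode pseudomarkers on a cM grid are tested via expected
    dosage from the flanking markers.  ``min_strains`` guards against
    underpowered panels; lower it only for worked examples.
    """
    rows, y = _align(pheno, geno, min_strains)
    if mode == "marker":
        info, D = marker_dosage(geno, rows)
    elif mode == "interval":
        info, D = interval_dosage(geno, rows, grid_cM)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_used, lrs, slope, flags = _scan_columns(y, D)
    table = info.copy()
    table["n"] = n_used
    table["LRS"] = lrs
    table["LOD"] = lrs / TWO_LN10
    table["additive_effect"] = slope
    table["flag"] = flags
    n_deg = int((flags == "degenerate").sum())
    if n_deg:
        logger.info("skipped %d degenerate loci", n_deg)
    return ScanResult(table=table, mode=mode)


def permutation_thresholds(
    pheno, geno: GenotypeMatrix, n_perm: int = 10000, seed: int = 0
) -> PermutationThresholds:
    """Genome-wide LRS thresholds from phenotype permutations.

    Strain phenotype values are shuffled against strain genotype rows; the
    per-permutation maximum LRS over all markers forms the null sample, and
    the thresholds are its empirical (1 - p) quantiles (inverse-ECDF
    quantile, i.e. an order statistic) at p = 0.05 and p = 0.63.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rows, y = _align(pheno, geno)
    _, D = marker_dosage(geno, rows)
    rng = np.random.default_rng(seed)
    if not np.isnan(D).any():
        null_max = _null_max_dense(y, D, n_perm, rng)
    else:
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            yp = rng.permutation(y)
            _, lrs, _, _ = _scan_columns(yp, D)
            null_max[p] = np.nanmax(lrs)
    sig = float(np.quantile(null_max, 1.0 - P_SIGNIFICANT, method="inverted_cdf"))
    sug = float(np.quantile(null_max, 1.0 - P_SUGGESTIVE, method="inverted_cdf"))
    return PermutationThresholds(significant=sig, suggestive=sug,
                                 null_max_lrs=null_max, n_perm=n_perm, seed=seed)


def _null_max_dense(y, D, n_perm, rng) -> np.ndarray:
    """Vectorized permutation null of the genome-wide max LRS (no missing)."""
    n = y.size
    yc = y - y.mean()
    ss0 = float(yc @ yc)
    if ss0 <= 0:
        return np.zeros(n_perm)
    Dc = D - D.mean(axis=0)
    sx = np.einsum("ij,ij->j", Dc, Dc)
    ok = sx > 1e-12
    Yp = rng.permuted(np.broadcast_to(yc, (n_perm, n)).copy(), axis=1)
    sxy = Dc[:, ok].T @ Yp.T  # markers x perms
    r2 = sxy**2 / (sx[ok, None] * ss0)
    lrs = -n * np.log(np.clip(1.0 - r2, LRS_EPS, None))
    return lrs.max(axis=0)


def genomewide_p(observed_lrs: float, null_sample: np.ndarray) -> float:
    """Permutation p-value (1 + #{null >= observed}) / (1 + n_perm)."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    return float((1 + np.sum(null_sample >= observed_lrs))
                 / (1 + null_sample.size))


def lod_drop_interval(scan: ScanResult, drop: float = 1.5) -> QTLInterval:
    """Support interval: widest contiguous run around the peak whose LOD
    stays within ``drop`` of the peak LOD, truncated at chromosome ends."""
    if len(scan.table) == 0:
        raise ValueError("empty scan")
    peak = scan.peak()
    chrom_tab = scan.table[scan.table["chrom"] == peak["chrom"]].reset_index(drop=True)
    lod = chrom_tab["LOD"].to_numpy()
    pk = int(np.flatnonzero(
        (chrom_tab["locus"] == peak["locus"]).to_numpy())[0])
    cut = peak["LOD"] - drop
    left = pk
    while left > 0 and np.isfinite(lod[left - 1]) and lod[left - 1] >= cut:
        left -= 1
    right = pk
    while right < len(lod) - 1 and np.isfinite(lod[right + 1]) and lod[right + 1] >= cut:
        right += 1
    return QTLInterval(
        chrom=str(peak["chrom"]), peak_locus=str(peak["locus"]),
        left_cM=float(chrom_tab.loc[left, "cM"]),
        right_cM=float(chrom_tab.loc[right, "cM"]),
        left_Mb=float(chrom_tab.loc[left, "Mb"]),
        right_Mb=float(chrom_tab.loc[right, "Mb"]),
        drop=drop,
    )


def bootstrap_peak(
    pheno, geno: GenotypeMatrix, n_boot: int = 2000, seed: int = 0
) -> pd.Series:
    """Frequency with which each locus harbors the genome-wide peak when
    strains are resampled with replacement.

    Degenerate resamples (fewer than two distinct strains, or no
    informative locus) are redrawn; the redraw count is recorded in
    ``result.attrs['n_redrawn']``.  Frequencies sum to one.
    """
    rows, y = _align(pheno, geno)
    info, D = marker_dosage(geno, rows)
    rng = np.random.default_rng(seed)
    m = D.shape[1]
    tally = np.zeros(m, dtype=int)
    n = y.size
    n_redrawn = 0
    drawn = 0
    while drawn < n_boot:
        pick = rng.integers(0, n, size=n)
        if np.unique(pick).size < 2:
            n_redrawn += 1
            logger.info("degenerate bootstrap resample redrawn")
            continue
        _, lrs, _, _ = _scan_columns(y[pick], D[pick])
        if np.all(np.isnan(lrs)):
            n_redrawn += 1
            continue
        tally[int(np.nanargmax(lrs))] += 1
        drawn += 1
    freq = pd.Series(tally / n_boot, index=info["locus"].to_numpy())
    freq.attrs["n_redrawn"] = n_redrawn
    return freq


def composite_scan(
    pheno, geno: GenotypeMatrix, control_markers: list[str],
    mode: str = "marker", grid_cM: float = 1.0,
) -> ScanResult:
    """Genome scan with marker genotypes as covariates.

    The control genotypes enter both the null (covariates only) and full
    (covariates + test locus) models, so LRS measures the test locus's
    contribution after removing variance associated with the controls.
    Strains missing any control genotype are dropped throughout; test loci
    collinear with the controls (e.g. the control marker itself) are
    reported with LRS 0 and the flag ``collinear``.
    """
    if not control_markers:
        return scan_single(pheno, geno, mode=mode, grid_cM=grid_cM)
    rows, y = _align(pheno, geno)
    Z = np.column_stack([geno.dosage(m)[rows] for m in control_markers])
    keep = ~np.isnan(Z).any(axis=1)
    if keep.sum() < 8:
        raise ValueError("fewer than 8 strains genotyped at all control markers")
    rows, y, Z = rows[keep], y[keep], Z[keep]
    if mode == "marker":
        info, D = marker_dosage(geno, rows)
    else:
        info, D = interval_dosage(geno, rows, grid_cM)
    n = y.size
    Z1 = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(Z1, y, rcond=None)
    y_r = y - Z1 @ beta
    rss_null = float(y_r @ y_r)

    m = D.shape[1]
    lrs = np.full(m, np.nan)
    slope = np.full(m, np.nan)
    n_used = np.full(m, n)
    flags = np.full(m, "", dtype=object)
    scale = float(np.mean(np.nanvar(D, axis=0)) + 1e-12)
    col_nan = np.isnan(D).any(axis=0)
    # residualize clean columns jointly (Frisch-Waugh-Lovell)
    clean = np.flatnonzero(~col_nan)
    if clean.size:
        G, *_ = np.linalg.lstsq(Z1, D[:, clean], rcond=None)
        Dr = D[:, clean] - Z1 @ G
        sx = np.einsum("ij,ij->j", Dr, Dr)
        collinear = sx <= 1e-9 * n * scale
        sxy = Dr.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            sl = sxy / sx
            r2 = sxy**2 / (sx * rss_null) if rss_null > 0 else np.zeros_like(sx)
        l = -float(n) * np.log(np.clip(1.0 - r2, LRS_EPS, None))
        l[collinear] = 0.0
        sl[collinear] = np.nan
        if rss_null <= 0:
            l[:] = 0.0
        lrs[clean], slope[clean] = l, sl
        flags[clean] = np.where(collinear, "collinear", "")
    for j in np.flatnonzero(col_nan):
        mask = ~np.isnan(D[:, j])
        nj = int(mask.sum())
        n_used[j] = nj
        if nj < 8:
            flags[j] = "degenerate"
            continue
        lrs[j], slope[j], flags[j] = _composite_locus(y[mask], Z[mask], D[mask, j])
    table = info.copy()
    table["n"] = n_used
    table["LRS"] = lrs
    table["LOD"] = lrs / TWO_LN10
    table["additive_effect"] = slope
    table["flag"] = flags
    return ScanResult(table=table, mode=mode)


def _composite_locus(y, Z, x):
    n = y.size
    Z1 = np.column_stack([np.ones(n), Z])
    X1 = np.column_stack([Z1, x])
    rss_null = _rss(Z1, y)
    if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(Z1):
        return 0.0, np.nan, "collinear"
    rss_full = _rss(X1, y)
    if rss_null <= 0:
        return 0.0, 0.0, ""
    frac = max(rss_full / rss_null, LRS_EPS)
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return float(-n * np.log(frac)), float(beta[-1]), ""


def _rss(X, y) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def fit_two_qtl(pheno, geno: GenotypeMatrix, marker1: str, marker2: str,
                min_strains: int = 8) -> TwoQTLFit:
    """Joint two-locus fit with an epistatic product term.

    Model: y = mu + a1*x1 + a2*x2 + i*x1*x2 over strains complete at both
    markers.  ``total_LRS`` compares the full model with the mean-only
    null; ``interaction_LRS`` with the additive model; each locus's
    ``additive_LRS`` and ``variance_explained`` are sequential after the
    other locus.  If the product column is confounded with the main
    effects the interaction term is dropped and flagged.
    """
    s = pd.Series(pheno).astype(float)
    x1_all = geno.dosage(marker1)
    x2_all = geno.dosage(marker2)
    names = np.array(geno.strains)
    in_pheno = np.isin(names, s.index[np.isfinite(s)])
    mask = in_pheno & ~np.isnan(x1_all) & ~np.isnan(x2_all)
    if mask.sum() < min_strains:
        raise ValueError(
            f"fewer than {min_strains} strains complete at both markers")
    y = s[names[mask]].to_numpy(dtype=float)
    x1, x2 = x1_all[mask], x2_all[mask]
    n = y.size
    one = np.ones(n)
    X0 = one[:, None]
    Xa = np.column_stack([one, x1, x2])
    Xf = np.column_stack([one, x1, x2, x1 * x2])
    flags: list[str] = []
    interaction_dropped = False
    if np.linalg.matrix_rank(Xf) < 4:
        interaction_dropped = True
        flags.append("interaction_confounded")
        Xf = Xa

    rss0 = _rss(X0, y)
    rss_add = _rss(Xa, y)
    rss_full = _rss(Xf, y)
    rss1only = _rss(np.column_stack([one, x1]), y)
    rss2only = _rss(np.column_stack([one, x2]), y)

    scale = max(rss0, 1.0) * 1e-12  # both-RSS-zero guard

    def _lrs(num, den):
        if num <= scale:
            return 0.0
        frac = min(max(den / num, LRS_EPS), 1.0)  # clamp numerical overshoot
        return float(-n * np.log(frac))

    total = _lrs(rss0, rss_full)
    interaction = 0.0 if interaction_dropped else _lrs(rss_add, rss_full)
    additive = {marker1: _lrs(rss2only, rss_add), marker2: _lrs(rss1only, rss_add)}
    var_exp = {
        marker1: (rss2only - rss_add) / rss0 if rss0 > 0 else 0.0,
        marker2: (rss1only - rss_add) / rss0 if rss0 > 0 else 0.0,
    }
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    coeffs = {"intercept": float(beta[0]), "a1": float(beta[1]),
              "a2": float(beta[2]),
              "i": float("nan") if interaction_dropped else float(beta[3])}
    return TwoQTLFit(marker1=marker1, marker2=marker2, n=n, total_LRS=total,
                     additive_LRS=additive, interaction_LRS=interaction,
                     coefficients=coeffs, variance_explained=var_exp,
                     interaction_dropped=interaction_dropped, flags=flags)


def thin_markers(gmap: GenoMap, thin_cM: float) -> list[str]:
    """One marker per ``thin_cM`` window within each chromosome."""
    keep = []
    for _, grp in gmap.table.groupby("chrom", sort=False):
        last = -np.inf
        for _, row in grp.iterrows():
            if row["cM"] >= last + thin_cM or not np.isfinite(last):
                keep.append(row["name"])
                last = row["cM"]
    return keep


def pairwise_scan(
    pheno, geno: GenotypeMatrix, thin_cM: float = 5.0, max_markers: int = 200
) -> pd.DataFrame:
    """Exhaustive two-locus scan over a thinned marker set.

    Fits :func:`fit_two_qtl` for every pair of distinct retained markers
    and ranks pairs by total LRS.  Raises if thinning leaves more than
    ``max_markers`` markers (quadratic cost guard).
    """
    markers = thin_markers(geno.gmap, thin_cM)
    if len(markers) > max_markers:
        raise ValueError(
            f"{len(markers)} markers after thinning exceeds cap {max_markers}; "
            "increase thin_cM or max_markers")
    rows = []
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1:]:
            try:
                fit = fit_two_qtl(pheno, geno, m1, m2)
            except ValueError:
                continue
            rows.append({
                "marker1": m1, "marker2": m2, "n": fit.n,
                "total_LRS": fit.total_LRS,
                "interaction_LRS": fit.interaction_LRS,
                "a1": fit.coefficients["a1"], "a2": fit.coefficients["a2"],
                "i": fit.coefficients["i"],
            })
    out = pd.DataFrame(rows).sort_values("total_LRS", ascending=False)
    return out.reset_index(drop=True)


def variance_explained(pheno, geno: GenotypeMatrix, marker: str) -> float:
    """R^2 of strain means on one marker's numeric genotype."""
    rows, y = _align(pheno, geno)
    x = geno.dosage(marker)[rows]
    mask = ~np.isnan(x)
    y, x = y[mask], x[mask]
    if np.unique(x).size < 2:
        raise ValueError(f"marker {marker!r} is degenerate on these strains")
    X = np.column_stack([np.ones(y.size), x])
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 <= 0:
        return 0.0
    return 1.0 - _rss(X, y) / rss0
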
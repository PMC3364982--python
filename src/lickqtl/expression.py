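"""Candidate-gene screening by partial correlation.

A strong correlation between a positional candidate's expression and the
phenotype can be an artifact of shared linkage to the QTL itself (or, for
microarrays, of probes overlapping sequence variants).  First-order partial
correlation controlling the QTL genotype removes the variance both traits
share with the locus:

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

with a two-sided p-value from the t transform on n - 2 - k degrees of
freedom for k control variables.  A candidate whose expression still
covaries with the phenotype after control is connected to it through
biology beyond the shared locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenotypeMatrix
from .scan import scan_single


@dataclass(frozen=True)
class ExpressionTrait:
    """Per-strain expression (log2 scale) for one probe/gene."""

    probe_id: str
    gene: str
    values: pd.Series  # index: strain
    annotation: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.Series):
            object.__setattr__(self, "values", pd.Series(self.values))


@dataclass(frozen=True)
class PartialCorrelation:
    r: float
    p: float
    n: int
    flag: str = ""


def partial_correlation(x, y, z) -> PartialCorrelation:
    """Partial Pearson correlation of x and y controlling z.

    ``z`` may be a single control vector or a (n, k) matrix; multi-control
    partials are computed as the correlation of the residuals of x and y
    after joint least-squares regression on the controls (equivalent to
    the recursive first-order formula for k = 1).  Collinear controls
    (|r_xz| = 1 or |r_yz| = 1) make the partial undefined; the result is
    flagged rather than raised so screens can report the row.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    k = z.shape[1]
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z).all(axis=1)
    x, y, z = x[mask], y[mask], z[mask]
    n = int(mask.sum())
    if n < k + 4:
        raise ValueError(f"need >= {k + 4} complete cases, have {n}")
    if np.allclose(z.std(axis=0), 0):
        raise ValueError("control variable is constant")

    Z1 = np.column_stack([np.ones(n), z])
    rx = x - Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]
    ry = y - Z1 @ np.linalg.lstsq(Z1, y, rcond=None)[0]
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    var_x = float(((x - x.mean()) ** 2).sum())
    var_y = float(((y - y.mean()) ** 2).sum())
    if var_x == 0 or var_y == 0:
        raise ValueError("x or y is constant")
    # collinear with control: residual variance vanishes
    if sx <= 1e-12 * var_x or sy <= 1e-12 * var_y:
        return PartialCorrelation(r=float("nan"), p=float("nan"), n=n,
                                  flag="collinear_control")
    r = float(rx @ ry / np.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return PartialCorrelation(r=r, p=0.0, n=n, flag="perfect")
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r=r, p=p, n=n)


def candidate_screen(
    pheno,
    expr: list[ExpressionTrait],
    geno: GenotypeMatrix,
    control_marker: str,
    min_strains: int = 5,
) -> pd.DataFrame:
    """Per-probe evidence table for positional candidates.

    For each probe: Pearson r of expression with the phenotype; the
    partial r and p controlling the numeric genotype at ``control_marker``;
    the probe's best-marker (cis) LRS from a genome scan of its expression;
    and the additive effect of genotype on expression (positive = D allele
    raises expression).  Probes with too few complete strains are flagged
    in place, never dropped silently.
    """
    s = pd.Series(pheno).astype(float)
    zx = pd.Series(geno.dosage(control_marker), index=geno.strains)
    rows = []
    for tr in expr:
        common = [st for st in tr.values.index
                  if st in s.index and st in zx.index]
        sub = pd.DataFrame({
            "expr": tr.values[common],
            "pheno": s[common],
            "z": zx[common],
        }).dropna()
        row = {"probe_id": tr.probe_id, "gene": tr.gene,
               "annotation": tr.annotation, "n": len(sub),
               "mean_expr": float(tr.values.mean()),
               "r": np.nan, "partial_r": np.nan, "partial_p": np.nan,
               "cis_marker": "", "cis_LRS": np.nan,
               "additive_effect": np.nan, "flag": ""}
        if len(sub) < min_strains:
            row["flag"] = "too_few_strains"
            rows.append(row)
            continue
        row["r"] = float(np.corrcoef(sub["expr"], sub["pheno"])[0, 1])
        try:
            pc = partial_correlation(sub["expr"], sub["pheno"], sub["z"])
            row["partial_r"], row["partial_p"] = pc.r, pc.p
            row["flag"] = pc.flag
        except ValueError as exc:
            row["flag"] = str(exc)
        try:
            res = scan_single(tr.values, geno)
            peak = res.peak()
            row["cis_marker"] = str(peak["locus"])
            row["cis_LRS"] = float(peak["LRS"])
            row["additive_effect"] = float(peak["additive_effect"])
        except ValueError:
            row["flag"] = (row["flag"] + ";no_scan").lstrip(";")
        rows.append(row)
    return pd.DataFrame(rows)


def read_expression(path, value_col: str = "value") -> list[ExpressionTrait]:
    """Read a long-format expression CSV (strain, probe, [gene], value)."""
    df = pd.read_csv(path)
    required = {"strain", "probe", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression file missing columns: {sorted(missing)}")
    traits = []
    for probe, grp in df.groupby("probe", sort=False):
        gene = str(grp["gene"].iloc[0]) if "gene" in grp.columns else ""
        traits.append(ExpressionTrait(
            probe_id=str(probe), gene=gene,
            values=pd.Series(grp[value_col].to_numpy(dtype=float),
                             index=grp["strain"].astype(str).to_numpy())))
    return traits
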
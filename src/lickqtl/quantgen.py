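"""Quantitative-genetic summaries for inbred strain panels.

Broad-sense heritability for a panel of inbred strains is estimated from a
one-way random-effects ANOVA of animal-level trait values grouped by strain
(Hegmann-Possidente form):

    h^2 = V_A / (V_A + 2 V_E)

with V_E the within-strain mean square and V_A the between-strain variance
component (MS_between - MS_within) / n0, where n0 is the effective
per-strain sample size for unbalanced designs.  The factor 2 reflects the
doubled additive variance among fully inbred lines relative to a randomly
mating population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StrainPhenotypeTable:
    """Animal-level phenotype records for a strain panel.

    ``data`` has one row per animal x stimulus with at least the columns
    ``animal`` and ``strain``; trait columns (``mpi``, ``total_licks``,
    ``vpl``, ``body_weight_g``, ...) are free-form.  Undefined phenotypes
    are NaN, never silently zero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("animal", "strain"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if self.data["strain"].nunique() < 1:
            raise ValueError("phenotype table has no strains")

    def trait_values(self, trait: str, stimulus: str | None = None) -> pd.DataFrame:
        """Rows with a defined value for ``trait`` (optionally one stimulus)."""
        df = self.data
        if stimulus is not None:
            df = df[df["stimulus"] == stimulus]
        return df[df[trait].notna()]

    def strain_means(self, trait: str, stimulus: str | None = None) -> pd.DataFrame:
        """Per-strain mean, SEM (sd/sqrt(n)) and n for one trait."""
        df = self.trait_values(trait, stimulus)
        g = df.groupby("strain")[trait]
        out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out[["mean", "sem", "n"]].reset_index()


@dataclass(frozen=True)
class VarianceComponents:
    """Between-strain (V_A) and within-strain (V_E) variance components.

    V_A is clamped at zero when the moment estimate is negative; ``n0`` is
    the effective per-strain sample size used in the V_A estimator.
    """

    V_A: float
    V_E: float
    n0: float
    n_strains: int
    n_animals: int


def variance_components(
    table: StrainPhenotypeTable | pd.DataFrame,
    trait: str,
    stimulus: str | None = None,
) -> VarianceComponents:
    """One-way random-effects ANOVA moment estimators on animal-level data.

    V_E = MS_within; V_A = (MS_between - MS_within) / n0 with
    n0 = (N - sum(n_i^2)/N) / (a - 1) for a strains and N animals
    (reduces to the common n_i for balanced designs).  Negative V_A
    estimates are clamped to zero.
    """
    if isinstance(table, pd.DataFrame):
        table = StrainPhenotypeTable(table)
    df = table.trait_values(trait, stimulus)
    groups = [g.to_numpy(dtype=float) for _, g in df.groupby("strain")[trait]]
    a = len(groups)
    if a < 2:
        raise ValueError("variance components require >= 2 strains")
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    if N - a == 0:
        raise ValueError("all strains have a single animal; V_E inestimable")

    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(n_i**2) / N) / (a - 1)
    v_a = max(0.0, (ms_between - ms_within) / n0)
    return VarianceComponents(V_A=v_a, V_E=ms_within, n0=float(n0),
                              n_strains=a, n_animals=N)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability h^2 = V_A / (V_A + 2 V_E) for inbred panels."""
    denom = vc.V_A + 2.0 * vc.V_E
    if denom <= 0:
        raise ValueError("V_A + 2*V_E must be positive")
    return vc.V_A / denom


def eta_squared(
    long_table: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    value: str = "value",
) -> float:
    """Repeated-measures effect size for a within-subject factor.

    eta^2 = SS_condition / (SS_total - SS_subjects): the share of variance
    explained by the condition after removing stable subject differences.
    Requires every subject observed in every condition.
    """
    df = long_table[[subject, condition, value]].dropna()
    pivot = df.pivot_table(index=subject, columns=condition, values=value,
                           aggfunc="count", fill_value=0)
    if not (pivot.to_numpy() == 1).all():
        raise ValueError("design unbalanced: every subject needs exactly one "
                         "observation per condition")
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    subj_means = df.groupby(subject)[value].mean()
    subj_n = df.groupby(subject)[value].count()
    ss_subject = float((subj_n * (subj_means - grand) ** 2).sum())
    cond_means = df.groupby(condition)[value].mean()
    cond_n = df.groupby(condition)[value].count()
    ss_condition = float((cond_n * (cond_means - grand) ** 2).sum())
    denom = ss_total - ss_subject
    if denom <= 0:
        raise ValueError("no within-subject variance to explain")
    return ss_condition / denom


def pearson_matrix(
    table: pd.DataFrame, traits: list[str], min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson correlation matrix over trait columns.

    Missing data are handled by pairwise-complete deletion; cells with
    fewer than ``min_pairs`` complete pairs are NaN (flagged undefined).
    """
    sub = table[traits].astype(float)
    return sub.corr(method="pearson", min_periods=min_pairs)
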
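"""Marker-trait association statistics.

Per-year one-way ANOVA F-tests between marker genotype groups, three-year
least-squares means from an additive genotype+year two-way model, Fisher's
exact test for score traits, and allele-frequency tabulation.  Group means
come with normal-theory 95% confidence intervals (t-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class AssocError(ValueError):
    pass


class InsufficientDataError(AssocError):
    pass


@dataclass
class PhenotypePanel:
    """Long-format phenotypes plus marker genotypes.

    ``phenotypes``: columns accession, year, trait, value (one row per
    accession x year x trait).  ``genotypes``: columns accession, marker,
    allele.
    """
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self):
        dup = self.phenotypes.duplicated(["accession", "year", "trait"])
        if dup.any():
            raise AssocError("duplicate accession x year x trait records")

    def merged(self, marker: str, trait: str) -> pd.DataFrame:
        geno = self.genotypes[self.genotypes["marker"] == marker]
        if geno.empty:
            raise AssocError(f"no genotypes for marker {marker!r}")
        phen = self.phenotypes[self.phenotypes["trait"] == trait]
        df = phen.merge(geno[["accession", "allele"]], on="accession",
                        how="inner")
        return df.dropna(subset=["value"])

    def write(self, phen_path, geno_path) -> None:
        self.phenotypes.to_csv(phen_path, sep="\t", index=False)
        self.genotypes.to_csv(geno_path, sep="\t", index=False)

    @classmethod
    def read(cls, phen_path, geno_path) -> "PhenotypePanel":
        return cls(pd.read_csv(phen_path, sep="\t"),
                   pd.read_csv(geno_path, sep="\t"))


@dataclass
class GroupStats:
    allele: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class AssocResult:
    trait: str
    year: object                     # a year, or "3-year LS mean"
    groups: list[GroupStats]
    f_statistic: float
    p_value: float

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def _group_stats(df: pd.DataFrame) -> list[GroupStats]:
    out = []
    for allele, sub in df.groupby("allele"):
        x = sub["value"].to_numpy(dtype=float)
        n = len(x)
        mean = float(np.mean(x))
        if n > 1:
            sem = float(np.std(x, ddof=1) / np.sqrt(n))
            half = float(stats.t.ppf(0.975, n - 1)) * sem
        else:
            half = np.nan
        out.append(GroupStats(str(allele), n, mean, mean - half,
                              mean + half))
    return out


def anova_per_year(panel: PhenotypePanel, marker: str, trait: str,
                   year) -> AssocResult:
    """One-way ANOVA F-test between genotype groups within one year."""
    df = panel.merged(marker, trait)
    df = df[df["year"] == year]
    groups = [sub["value"].to_numpy(dtype=float)
              for _, sub in df.groupby("allele")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(
            f"{trait}/{year}: need >= 2 genotype groups with >= 2 members")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):          # zero within-group variance with equal means
        f, p = 0.0, 1.0
    return AssocResult(trait=trait, year=year, groups=_group_stats(df),
                       f_statistic=float(f), p_value=float(p))


def lsmeans_two_way(panel: PhenotypePanel, marker: str,
                    trait: str) -> dict[str, float]:
    """Genotype least-squares means from an additive genotype+year model.

    The model value ~ genotype + year is solved by ordinary least squares;
    each genotype's LS mean averages its predictions over all year levels
    with equal weight.  With balanced data this reduces to the raw group
    means.  Inestimable genotypes (absent from the fit) raise an error.
    """
    import statsmodels.formula.api as smf

    df = panel.merged(marker, trait).copy()
    years = sorted(df["year"].unique())
    if len(years) < 1:
        raise InsufficientDataError("no year levels present")
    df["year"] = df["year"].astype("category")
    df["allele"] = df["allele"].astype("category")
    if df["allele"].nunique() < 2:
        raise InsufficientDataError("need >= 2 genotype groups")
    model = smf.ols("value ~ C(allele) + C(year)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise InsufficientDataError(
            "rank-deficient design: some genotype LS means are inestimable")
    out = {}
    for allele in df["allele"].cat.categories:
        grid = pd.DataFrame({
            "allele": pd.Categorical([allele] * len(years),
                                     categories=df["allele"].cat.categories),
            "year": pd.Categorical(years, categories=years),
        })
        out[str(allele)] = float(model.predict(grid).mean())
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric: sum of
    probabilities of tables as or less probable than the observed one)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise AssocError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise AssocError("table has an empty margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def score_trait_table(panel: PhenotypePanel, marker: str, trait: str,
                      year, carrier_allele: str) -> np.ndarray:
    """2x2 layout for score traits: carrier status x above/below median."""
    df = panel.merged(marker, trait)
    df = df[df["year"] == year]
    med = df["value"].median()
    carrier = df["allele"] == carrier_allele
    above = df["value"] > med
    return np.array([
        [int((carrier & above).sum()), int((carrier & ~above).sum())],
        [int((~carrier & above).sum()), int((~carrier & ~above).sum())],
    ])


def allele_frequency(panel: PhenotypePanel, marker: str) -> pd.DataFrame:
    """Carrier counts and percentages over non-missing accessions."""
    geno = panel.genotypes[panel.genotypes["marker"] == marker]
    if geno.empty:
        raise AssocError(f"no genotypes for marker {marker!r}")
    geno = geno.drop_duplicates("accession")
    missing = int(geno["allele"].isna().sum())
    called = geno.dropna(subset=["allele"])
    total = len(called)
    rows = []
    for allele, sub in called.groupby("allele"):
        rows.append({"allele": str(allele), "count": len(sub),
                     "percent": 100.0 * len(sub) / total})
    out = pd.DataFrame(rows).sort_values("count", ascending=False,
                                         ignore_index=True)
    out.attrs["missing"] = missing
    return out


def association_table(panel: PhenotypePanel, marker: str,
                      traits: list[str] | None = None,
                      bh_correction: bool = False) -> pd.DataFrame:
    """Per-trait, per-year F-test summary (raw p-values; optional
    Benjamini-Hochberg column, off by default)."""
    if traits is None:
        traits = sorted(panel.phenotypes["trait"].unique())
    years = sorted(panel.phenotypes["year"].unique())
    rows = []
    for trait in traits:
        for year in years:
            try:
                r = anova_per_year(panel, marker, trait, year)
            except InsufficientDataError:
                continue
            row = {"trait": trait, "year": year, "F": r.f_statistic,
                   "p": r.p_value}
            for g in r.groups:
                row[f"mean_{g.allele}"] = g.mean
                row[f"n_{g.allele}"] = g.n
            rows.append(row)
    df = pd.DataFrame(rows)
    if bh_correction and not df.empty:
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
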
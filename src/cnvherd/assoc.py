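"""Association of CNVR genotypes with growth traits.

Fits the additive fixed-effects model

    Y_ijk = mu + F_i + G_j + B_k + E_ijk

(farm, CNV genotype, breed) by ordinary least squares, then reports
least-squares means (LSM) of the genotype classes: the model prediction for a
genotype level averaged with equal weights over the grid of observed farm and
breed levels.  Pairwise genotype contrasts are t-tested on the residual
degrees of freedom and summarised as significance letters — levels sharing no
letter differ at the chosen alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

FACTORS = ("farm", "genotype", "breed")
TRAITS = ("body_height", "body_length", "heart_girth", "hucklebone_width", "body_weight")


@dataclass
class ModelFit:
    """A fitted trait model plus the pieces LSM needs."""

    trait: str
    result: object  # statsmodels RegressionResults
    data: pd.DataFrame  # rows actually used (trait non-missing)
    factors: tuple[str, ...]  # factors with >= 2 observed levels

    @property
    def df_resid(self) -> float:
        return float(self.result.df_resid)


def _check_aliasing(data: pd.DataFrame, factors: Sequence[str]) -> None:
    # two factors are aliased when the levels of one determine the other
    for fa, fb in itertools.combinations(factors, 2):
        tab = pd.crosstab(data[fa], data[fb])
        if ((tab > 0).sum(axis=1) == 1).all() or ((tab > 0).sum(axis=0) == 1).all():
            raise ValueError(
                f"factor {fa!r} is perfectly confounded with {fb!r}: "
                f"levels {sorted(data[fa].unique())} vs {sorted(data[fb].unique())}"
            )


def fit_model(records: pd.DataFrame, trait: str) -> ModelFit:
    """OLS fit of trait ~ farm + genotype + breed on the non-missing records.

    Factors with a single observed level are dropped from the formula (the
    model reduces accordingly).  Perfect confounding between factors is
    rejected with the aliased levels named.
    """
    for col in FACTORS:
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    if trait not in records.columns:
        raise ValueError(f"unknown trait {trait!r}")
    data = records.dropna(subset=[trait]).copy()
    if data.empty:
        raise ValueError(f"no records with trait {trait!r}")
    if (data[trait] <= 0).any():
        raise ValueError(f"trait {trait!r} has non-positive measurements")
    factors = tuple(f for f in FACTORS if data[f].nunique() > 1)
    if len(factors) >= 2:
        _check_aliasing(data, factors)
    rhs = " + ".join(f"C({f})" for f in factors) if factors else "1"
    result = smf.ols(f"{trait} ~ {rhs}", data=data).fit()
    rank = np.linalg.matrix_rank(result.model.exog)
    if rank < result.model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient (aliased factor levels)")
    return ModelFit(trait=trait, result=result, data=data, factors=factors)


@dataclass(frozen=True)
class LsmResult:
    """Least-squares mean of one genotype level with its standard error."""

    trait: str
    genotype: str
    n: int
    lsm: float
    se: float
    letter: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


def _lsm_contrast(fit: ModelFit, genotype: str) -> np.ndarray:
    """Equal-weight average design row over the observed farm x breed grid."""
    grid_factors = [f for f in fit.factors if f != "genotype"]
    levels = {f: sorted(fit.data[f].unique()) for f in grid_factors}
    combos = list(itertools.product(*(levels[f] for f in grid_factors))) or [()]
    rows = pd.DataFrame(
        [
            {"genotype": genotype, **dict(zip(grid_factors, combo))}
            for combo in combos
        ]
    )
    design_info = fit.result.model.data.design_info
    from patsy import build_design_matrices

    (X,) = build_design_matrices([design_info], rows)
    return np.asarray(X).mean(axis=0)


def lsm(fit: ModelFit) -> list[LsmResult]:
    """Least-squares mean and SE per genotype level.

    LSM(level) = c' beta with c the average design row over the farm x breed
    grid; SE = sqrt(c' Cov(beta) c).  With a balanced design this reduces to
    the raw genotype group means.
    """
    beta = np.asarray(fit.result.params)
    cov = np.asarray(fit.result.cov_params())
    out = []
    for level in sorted(fit.data["genotype"].unique()):
        c = _lsm_contrast(fit, level)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        n = int((fit.data["genotype"] == level).sum())
        out.append(LsmResult(fit.trait, str(level), n, est, se))
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    estimate: float  # LSM(a) - LSM(b)
    se: float
    t_statistic: float
    p_value: float


def pairwise_contrasts(fit: ModelFit) -> list[PairwiseComparison]:
    """t-tests on all pairwise genotype LSM differences (residual df)."""
    beta = np.asarray(fit.result.params)
    cov = np.asarray(fit.result.cov_params())
    levels = sorted(fit.data["genotype"].unique())
    contrasts = {g: _lsm_contrast(fit, g) for g in levels}
    out = []
    for a, b in itertools.combinations(levels, 2):
        d = contrasts[a] - contrasts[b]
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
        out.append(PairwiseComparison(str(a), str(b), est, se, t, p))
    return out


def _letter_display(levels: Sequence[str], nonsig: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display: maximal cliques of the not-different graph.

    Enumerated exactly (genotype level counts are tiny); cliques are lettered
    in order of their best-ranked member so the display is deterministic.
    """
    n = len(levels)
    cliques: list[tuple[str, ...]] = []
    for size in range(n, 0, -1):
        for combo in itertools.combinations(levels, size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(frozenset((a, b)) in nonsig for a, b in itertools.combinations(combo, 2)):
                cliques.append(combo)
    rank = {lvl: i for i, lvl in enumerate(levels)}
    cliques.sort(key=lambda c: min(rank[l] for l in c))
    letters: dict[str, str] = {lvl: "" for lvl in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lvl in clique:
            letters[lvl] += ch
    return letters


def compare_levels(
    fit: ModelFit,
    lsm_results: Sequence[LsmResult],
    alpha: float = 0.05,
) -> tuple[list[LsmResult], list[PairwiseComparison]]:
    """Assign significance letters to LSM results at the given alpha.

    Levels sharing no letter differ at ``alpha``; no multiplicity correction
    is applied (apply :func:`cnvherd.groups.benjamini_hochberg` to the
    returned p-values to get an adjusted display).
    """
    if len(lsm_results) < 2:
        raise ValueError("need at least two genotype levels to compare")
    comps = pairwise_contrasts(fit)
    nonsig = {
        frozenset((c.level_a, c.level_b)) for c in comps if c.p_value >= alpha
    }
    order = [r.genotype for r in sorted(lsm_results, key=lambda r: -r.lsm)]
    letters = _letter_display(order, nonsig)
    lettered = [
        LsmResult(r.trait, r.genotype, r.n, r.lsm, r.se, letters[r.genotype])
        for r in lsm_results
    ]
    return lettered, comps


def association_table(
    records: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Trait x genotype LSM +/- SE table with significance letters.

    One row per (trait, genotype level): N, LSM, SE, letter.  Traits absent
    from the records are skipped with a warning.
    """
    rows = []
    for trait in traits:
        if trait not in records.columns:
            warnings.warn(f"trait {trait!r} missing from records; skipped", stacklevel=2)
            continue
        fit = fit_model(records, trait)
        lettered, _ = compare_levels(fit, lsm(fit), alpha=alpha)
        for r in lettered:
            rows.append((trait, r.genotype, r.n, r.lsm, r.se, r.letter))
    return pd.DataFrame(rows, columns=["trait", "genotype", "n", "lsm", "se", "letters"])
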
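"""Broad-sense heritability and variance partitioning of growth traits.

Heritability H^2 = sigma^2_G / (sigma^2_G + sigma^2_E) is estimated at each
relative-time grid point from a one-way random-effects model (genotype as
random intercept, REML).  Variance is partitioned across environment,
development (categorical stage), genotype and all their interactions by
multifactorial ANOVA with sequential (type I) sums of squares, each term
reported as a percentage of the total sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .devtime import grid_columns

__all__ = [
    "HeritabilityEstimate",
    "estimate_h2",
    "h2_trajectory",
    "variance_partition",
    "trait_correlation",
    "ANOVA_TERMS",
]

ANOVA_TERMS = [
    "Environment", "Development", "Genotype",
    "Env:Dev", "Env:Geno", "Dev:Geno", "Env:Dev:Geno",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    grid_point: float
    sigma2_g: float
    sigma2_e: float
    h2: float
    n_plants: int
    n_genotypes: int


def _check_design(genotypes: np.ndarray) -> None:
    labels, counts = np.unique(genotypes, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 genotypes")
    if counts.max() < 2:
        raise ValueError("need at least one genotype with >= 2 replicates")


def estimate_h2(
    values,
    genotypes,
    trait: str = "trait",
    grid_point: float = np.nan,
) -> HeritabilityEstimate:
    """Broad-sense heritability from a one-way random-effects model (REML).

    Genotype enters as a random intercept; variance components are truncated
    at zero before forming H^2 = sigma^2_G / (sigma^2_G + sigma^2_E).  The
    estimator is invariant to affine rescaling of the trait.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(genotypes)
    if y.size != g.size:
        raise ValueError("values and genotype labels must be parallel")
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    _check_design(g)
    labels = np.unique(g)

    # boundary guard: zero within-genotype variance defeats REML iteration
    within = sum(float(((y[g == lab] - y[g == lab].mean()) ** 2).sum()) for lab in labels)
    total = float(((y - y.mean()) ** 2).sum())
    if total <= 0:
        sigma_g, sigma_e = 0.0, 0.0
        h2 = 0.0
    elif within <= 1e-12 * total:
        sigma_e = 0.0
        sigma_g = float(np.var([y[g == lab].mean() for lab in labels], ddof=1))
        h2 = 1.0
    else:
        exog = np.ones((y.size, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=g)
            res = model.fit(reml=True)
        sigma_g = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        sigma_e = max(float(res.scale), 0.0)
        h2 = sigma_g / (sigma_g + sigma_e) if sigma_g + sigma_e > 0 else 0.0
    return HeritabilityEstimate(
        trait=trait, grid_point=grid_point, sigma2_g=sigma_g, sigma2_e=sigma_e,
        h2=float(np.clip(h2, 0.0, 1.0)), n_plants=int(y.size), n_genotypes=int(labels.size),
    )


def h2_trajectory(table: pd.DataFrame, trait: str) -> tuple[list[HeritabilityEstimate], dict]:
    """Heritability at every grid point of a phenotype table for one trait.

    ``table`` is the output of ``assemble_phenotype_table``.  Returns the
    per-point estimates plus a summary (median, peak value, peak position).
    Grid points where any plant is missing are skipped.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    cols = [c for c in sub.columns if c.startswith("g") and c[1:].isdigit()]
    grid = np.linspace(0.0, 1.0, len(cols))
    estimates = []
    for col, gp in zip(cols, grid):
        y = sub[col].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            continue
        estimates.append(estimate_h2(y, sub["accession"].to_numpy(), trait=trait, grid_point=float(gp)))
    if not estimates:
        raise ValueError(f"no fully covered grid points for trait {trait!r}")
    h2s = np.array([e.h2 for e in estimates])
    peak = int(np.argmax(h2s))
    summary = {
        "median": float(np.median(h2s)),
        "peak": float(h2s[peak]),
        "peak_position": float(estimates[peak].grid_point),
        "n_points": len(estimates),
    }
    return estimates, summary


def variance_partition(long: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Multifactorial variance partition with sequential sums of squares.

    ``long`` needs columns environment, development, genotype and the trait
    value; development is treated as a categorical stage.  The model is
    y ~ Env + Dev + Geno + Env:Dev + Env:Geno + Dev:Geno + Env:Dev:Geno,
    fitted by OLS with type-I ANOVA in that term order.  Each term's percent
    variance is its sum of squares over the total sum of squares; p-values
    come from the F tests.  Returns a DataFrame indexed by term (plus
    Residual) with columns percent_variance and p.
    """
    required = {"environment", "development", "genotype", value_col}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for col in ("environment", "development", "genotype"):
        if long[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    df = long.rename(columns={value_col: "y"}).copy()
    formula = (
        "y ~ C(environment) + C(development) + C(genotype)"
        " + C(environment):C(development) + C(environment):C(genotype)"
        " + C(development):C(genotype)"
        " + C(environment):C(development):C(genotype)"
    )
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=1)
    if table["df"].le(0).any() or not np.isfinite(table["sum_sq"]).all():
        bad = table.index[table["df"].le(0) | ~np.isfinite(table["sum_sq"])].tolist()
        raise ValueError(f"aliased design; confounded terms: {bad}")
    total_ss = float(table["sum_sq"].sum())
    name_map = {
        "C(environment)": "Environment",
        "C(development)": "Development",
        "C(genotype)": "Genotype",
        "C(environment):C(development)": "Env:Dev",
        "C(environment):C(genotype)": "Env:Geno",
        "C(development):C(genotype)": "Dev:Geno",
        "C(environment):C(development):C(genotype)": "Env:Dev:Geno",
        "Residual": "Residual",
    }
    out = pd.DataFrame({
        "term": [name_map.get(ix, ix) for ix in table.index],
        "percent_variance": 100.0 * table["sum_sq"].to_numpy() / total_ss,
        "p": table["PR(>F)"].to_numpy(),
    }).set_index("term")
    return out


def trait_correlation(table: pd.DataFrame, trait_a: str, trait_b: str) -> tuple[pd.DataFrame, dict]:
    """Per-grid-point Pearson correlation between two traits across plants.

    Both traits must cover the same plants on the same grid.  Points with
    zero variance in either trait are reported as NaN.  Returns the per-point
    table and a range summary (min, max over finite points).
    """
    a = table[table["trait"] == trait_a].set_index("plant_id").sort_index()
    b = table[table["trait"] == trait_b].set_index("plant_id").sort_index()
    if a.empty or b.empty:
        raise ValueError("both traits must be present in the table")
    if list(a.index) != list(b.index):
        raise ValueError("traits must cover the same plants")
    cols = [c for c in table.columns if c.startswith("g") and c[1:].isdigit()]
    grid = np.linspace(0.0, 1.0, len(cols))
    rows = []
    for col, gp in zip(cols, grid):
        x = a[col].to_numpy(dtype=float)
        y = b[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x[ok], y[ok]).statistic)
        rows.append({"grid_point": float(gp), "r": r})
    out = pd.DataFrame(rows)
    finite = out["r"].dropna()
    summary = {"r_min": float(finite.min()) if len(finite) else np.nan,
               "r_max": float(finite.max()) if len(finite) else np.nan}
    return out, summary
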
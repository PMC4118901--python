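"""Marker-trait association under a structured-population GLM.

Trait descriptive statistics and across-line ANOVA, pairwise Pearson
correlations, a minor-allele-frequency filter, and the fixed-effects
linear model ``trait ~ intercept + Q + variant`` with the marker tested
by a partial F-test of the full model against the Q-only model.  Marker
R^2 is the incremental variance fraction (SSE_reduced - SSE_full) /
SS_total.  Allele classes are additionally compared with a two-sample
t-test (Welch by default).

Association runs on per-line trait means; replicates, when present, feed
the ANOVA only.  Inbred lines are haploid haplotypes: each variant enters
the model as a 0/1 major/minor contrast after MAF filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import PhenotypeTable, QMatrix, logger
from .variant_scan import MISSING, Variant, VariantTable


# ---------------------------------------------------------------------------
# trait summaries
# ---------------------------------------------------------------------------

def trait_summaries(phen: PhenotypeTable) -> pd.DataFrame:
    """Descriptive statistics over line means plus one-way ANOVA across
    lines using replicates (F is NaN without replication)."""
    means = phen.line_means()
    rows = []
    has_reps = phen.data.groupby("line").size().max() > 1
    for trait in phen.traits:
        col = means[trait].dropna()
        F = p = float("nan")
        if has_reps:
            groups = [g.dropna().to_numpy() for _, g in phen.data.groupby("line")[trait]]
            groups = [g for g in groups if len(g) > 0]
            sds = [g.std(ddof=1) for g in groups if len(g) > 1]
            if sds and np.allclose(sds, 0):
                logger.warning("trait %s has zero within-line variance; ANOVA F unbounded", trait)
                F, p = np.finfo(float).max, 0.0
            else:
                F, p = stats.f_oneway(*groups)
        rows.append({"trait": trait, "mean": col.mean(), "sd": col.std(ddof=1),
                     "min": col.min(), "max": col.max(), "F": float(F), "p": float(p)})
    return pd.DataFrame(rows)


def trait_correlations(phen: PhenotypeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over line means.  Constant
    traits yield NaN (correlation undefined)."""
    means = phen.line_means()
    traits = phen.traits
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            sub = means[[traits[i], traits[j]]].dropna()
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                continue
            r[i, j], p[i, j] = stats.pearsonr(x, y)
            r[j, i], p[j, i] = r[i, j], p[i, j]
    return (pd.DataFrame(r, index=traits, columns=traits),
            pd.DataFrame(p, index=traits, columns=traits))


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def maf_filter(vt: VariantTable, threshold: float = 0.05) -> VariantTable:
    """Drop alleles with frequency strictly below ``threshold`` (an allele
    at exactly the threshold is retained).

    Samples carrying a dropped allele become missing for that variant;
    variants left with fewer than two alleles are removed.  Frequencies
    are computed over called samples.
    """
    kept: list[Variant] = []
    for v in vt.variants:
        counts = v.counts
        n_called = sum(counts.values())
        if n_called == 0:
            continue
        keep = [a for a in v.alleles if counts[a] / n_called >= threshold]
        if len(keep) < 2:
            logger.info("MAF filter: %s removed (%d allele(s) left)", v.id, len(keep))
            continue
        geno = v.genotypes.copy()
        dropped = [a for a in v.alleles if a not in keep]
        for a in dropped:
            geno[geno == a] = MISSING
        if dropped:
            logger.info("MAF filter: %s dropped allele(s) %s", v.id, dropped)
        kept.append(Variant(v.id, v.kind, v.position, v.span, keep, geno,
                            v.region, v.site_class, v.coding_effect))
    return VariantTable(list(vt.sample_ids), kept)


# ---------------------------------------------------------------------------
# GLM association
# ---------------------------------------------------------------------------

@dataclass
class AssociationScan:
    results: pd.DataFrame  # long format, one row per (variant, trait)

    def top(self, trait: str) -> pd.Series:
        sub = self.results[self.results["trait"] == trait].dropna(subset=["p"])
        return sub.loc[sub["p"].idxmin()]


def _variant_contrast(v: Variant) -> np.ndarray:
    """0/1 major/minor coding over the two most frequent alleles; other
    alleles (already rare after MAF filtering) and missing are NaN."""
    x = np.full(len(v.genotypes), np.nan)
    x[v.genotypes == v.alleles[0]] = 0.0
    x[v.genotypes == v.alleles[1]] = 1.0
    return x


def glm_single(y: np.ndarray, x: np.ndarray, q_cols: np.ndarray) -> dict[str, float]:
    """Partial F-test of one 0/1 marker given Q covariates.

    Fits ``y ~ 1 + Q`` and ``y ~ 1 + Q + x`` by OLS; returns F, p, the
    incremental marker R^2 and the fitted allele effect.  A marker
    collinear with the covariates is flagged with NaN p.
    """
    n = len(y)
    X_red = sm.add_constant(q_cols, has_constant="add")
    X_full = np.column_stack([X_red, x])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_red):
        return {"F": float("nan"), "p": float("nan"), "marker_r2": float("nan"),
                "effect": float("nan"), "flagged": True}
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_resid = n - X_full.shape[1]
    if df_resid <= 0 or full.ssr <= 0:
        return {"F": float("nan"), "p": float("nan"), "marker_r2": float("nan"),
                "effect": float("nan"), "flagged": True}
    F = (red.ssr - full.ssr) / (full.ssr / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    marker_r2 = (red.ssr - full.ssr) / ss_total if ss_total > 0 else float("nan")
    return {"F": float(F), "p": p, "marker_r2": float(marker_r2),
            "effect": float(full.params[-1]), "flagged": False}


def allele_class_test(
    values0: np.ndarray, values1: np.ndarray, welch: bool = True
) -> dict[str, float]:
    """Two-sample t-test between the two allele classes (Welch by
    default; pooled-variance via ``welch=False``), with per-class mean
    and sd."""
    t, p = stats.ttest_ind(values0, values1, equal_var=not welch)
    return {
        "mean0": float(np.mean(values0)), "sd0": float(np.std(values0, ddof=1)),
        "mean1": float(np.mean(values1)), "sd1": float(np.std(values1, ddof=1)),
        "t": float(t), "t_p": float(p),
    }


def glm_association(
    vt: VariantTable,
    phen: PhenotypeTable,
    q: QMatrix,
    traits: list[str] | None = None,
    maf: float | None = 0.05,
    welch: bool = True,
    marginal_r2: bool = False,
) -> AssociationScan:
    """Scan every (variant, trait) pair with the Q-covariate GLM.

    Samples are intersected across the variant table, phenotypes and Q
    matrix; each variant uses its non-missing subset.  Raw p-values are
    reported with a Bonferroni-adjusted column alongside.  With
    ``marginal_r2=True`` the marker R^2 ignores Q (single-marker model)
    instead of the default partial (after-Q) definition.
    """
    if maf is not None:
        vt = maf_filter(vt, maf)
    traits = traits or phen.traits
    shared = [s for s in vt.sample_ids if s in set(phen.sample_ids) & set(q.sample_ids)]
    if len(shared) < len(vt.sample_ids):
        logger.warning("association: %d of %d panel samples have phenotype+Q",
                       len(shared), len(vt.sample_ids))
    idx = [vt.sample_ids.index(s) for s in shared]
    q_cols = q.restrict(shared).design_columns()
    means = phen.line_means().loc[shared]

    rows = []
    for v in vt.variants:
        x_all = _variant_contrast(v)[idx]
        for trait in traits:
            y_all = means[trait].to_numpy(dtype=float)
            ok = ~np.isnan(x_all) & ~np.isnan(y_all)
            x, y_sub = x_all[ok], y_all[ok]
            rec = {"variant": v.id, "trait": trait, "n": int(ok.sum()),
                   "allele0": v.alleles[0], "allele1": v.alleles[1]}
            if len(np.unique(x)) < 2:
                rec.update({"F": np.nan, "p": np.nan, "marker_r2": np.nan,
                            "effect": np.nan, "flagged": True})
            else:
                qc = q_cols[ok] if q_cols.size else np.empty((int(ok.sum()), 0))
                rec.update(glm_single(y_sub, x, qc))
                if marginal_r2:
                    rec["marker_r2"] = glm_single(y_sub, x, np.empty((len(x), 0)))["marker_r2"]
                rec.update(allele_class_test(y_sub[x == 0], y_sub[x == 1], welch=welch))
            rows.append(rec)
    df = pd.DataFrame(rows)
    m = df["p"].notna().sum()
    df["p_bonferroni"] = np.minimum(df["p"] * m, 1.0)
    logger.info("association scan: %d variants x %d traits (%d tests)",
                len(vt.variants), len(traits), m)
    return AssociationScan(df)
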
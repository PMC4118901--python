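"""Nucleotide diversity and neutrality tests.

Per-region and pooled estimates of nucleotide diversity (pi), Watterson's
theta, Tajima's D and Fu & Li's starred statistics D* and F* (the
no-outgroup forms) on a gapped alignment panel.

Gap handling follows the "complete deletion of indel columns" convention:
every statistic is computed over the region's gap-free columns only, so
the effective (net) length is the gross region length minus the columns
spanned by indel events.  Singletons entering the Fu & Li tests count
singleton SNP mutations only; indel events never contribute to S, pi or
the test statistics.

Significance:

* Tajima's D — the beta-distribution approximation from the statistic's
  original construction (D rescaled onto its attainable range, shape
  parameters fixed by zero mean and unit variance);
* D*/F* — two-sided critical values frozen from a neutral-coalescent
  simulation (fixed number of segregating sites, no recombination),
  linearly interpolated in n.  These are approximations adequate for
  flagging, not exact p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GAP, MISSING_BASE, AlignedPanel, GeneModel, logger
from .variant_scan import VariantTable, gap_columns


# ---------------------------------------------------------------------------
# sample-size constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityConstants:
    """All sample-size-only constants of the neutrality tests.

    ``a1``..``e2`` are the variance constants of Tajima's D; ``u_dstar``/
    ``v_dstar`` weight the D* variance (corrected forms) and ``u_fstar``/
    ``v_fstar`` the F* variance (original published forms — the pairing
    that matches standard software output).
    """

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    u_dstar: float
    v_dstar: float
    u_fstar: float
    v_fstar: float


@lru_cache(maxsize=None)
def neutrality_constants(n: int) -> NeutralityConstants:
    """Compute every constant for sample size ``n`` (n >= 3 for the
    starred tests; a1 alone needs only n >= 2)."""
    if n < 2:
        raise ValueError("sample size must be at least 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if n >= 3:
        an1 = a1 + 1.0 / n  # a_{n+1}
        cn = 2.0 * (n * a1 - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
        dn = (cn + (n - 2.0) / (n - 1) ** 2
              + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2.0) - 1.0 / n))
        v_dstar = (((n / (n - 1.0)) ** 2) * a2 + a1**2 * dn
                   - 2 * (n * a1 * (a1 + 1)) / (n - 1.0) ** 2) / (a1**2 + a2)
        u_dstar = (n / (n - 1.0)) * (a1 - n / (n - 1.0)) - v_dstar
        v_fstar = ((2 * n**3 + 110 * n**2 - 255 * n + 153) / (9.0 * n**2 * (n - 1))
                   + (2 * (n - 1) * a1) / n**2 - 8.0 * a2 / n) / (a1**2 + a2)
        u_fstar = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1)
                   / (3.0 * n * (n - 1))) / a1 - v_fstar
    else:
        u_dstar = v_dstar = u_fstar = v_fstar = float("nan")
    return NeutralityConstants(n, a1, a2, b1, b2, c1, c2, e1, e2,
                               u_dstar, v_dstar, u_fstar, v_fstar)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def pairwise_pi(panel: AlignedPanel, columns: np.ndarray | list[int]) -> float:
    """Per-site nucleotide diversity over a set of 1-based columns.

    Averages, over all sample pairs, the per-site mismatch fraction
    computed on the columns where both sequences have a called base
    (pairwise handling of missing data).  With no missing data this is
    exactly sum(d_ij) / C(N,2) / L_net.  Returns NaN when the column set
    is empty.
    """
    cols = np.asarray(columns, dtype=int)
    if cols.size == 0:
        return float("nan")
    sub = panel.columns(cols)
    n = sub.shape[0]
    called = sub != MISSING_BASE
    total, n_pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            L_ij = int(shared.sum())
            if L_ij == 0:
                continue
            d_ij = int(np.sum((sub[i] != sub[j]) & shared))
            total += d_ij / L_ij
            n_pairs += 1
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs


def watterson_theta(S: int, n: int, L_net: float) -> float:
    """Watterson's per-site estimator theta_w = S / (a1 * L_net)."""
    if L_net <= 0:
        return float("nan")
    return S / (neutrality_constants(n).a1 * L_net)


def tajimas_d(pi: float, S: int, n: int, L_net: float) -> float:
    """Tajima's D from per-site pi, segregating sites S and net length.

    Undefined (NaN) when S = 0 — the variance term vanishes.
    """
    if S <= 0:
        return float("nan")
    c = neutrality_constants(n)
    kbar = pi * L_net
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (kbar - S / c.a1) / np.sqrt(var)


def fu_li_star(S: int, eta_s: int, pi: float, n: int, L_net: float) -> tuple[float, float]:
    """Fu & Li's D* and F* (no outgroup) from S, singleton count, per-site
    pi and net length.  Returns (NaN, NaN) when S = 0."""
    if S <= 0:
        return float("nan"), float("nan")
    c = neutrality_constants(n)
    kbar = pi * L_net
    dstar = ((n / (n - 1.0)) * S - c.a1 * eta_s) / np.sqrt(c.u_dstar * S + c.v_dstar * S**2)
    fstar = (kbar - ((n - 1.0) / n) * eta_s) / np.sqrt(c.u_fstar * S + c.v_fstar * S**2)
    return float(dstar), float(fstar)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def tajima_d_pvalue(D: float, n: int) -> float:
    """Two-sided p-value for Tajima's D via the beta approximation.

    D is assumed to follow a generalized beta distribution over its
    attainable range [D_min, D_max] with mean 0 and variance 1, the
    approximation proposed with the statistic itself.
    """
    if not np.isfinite(D):
        return float("nan")
    c = neutrality_constants(n)
    dmin = (2.0 / n - 1.0 / c.a1) / np.sqrt(c.e2)
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / c.a1) / np.sqrt(c.e2)
    # shape parameters fixed by E[D]=0, Var[D]=1 on [dmin, dmax]
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if alpha <= 0 or beta <= 0 or not (dmin < D < dmax):
        return 0.0 if not (dmin < D < dmax) else float("nan")
    u = (D - dmin) / (dmax - dmin)
    cdf = stats.beta.cdf(u, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


#: two-sided critical values for D* and F*, frozen from a 20,000-replicate
#: neutral-coalescent simulation (fixed S=20, no recombination), keyed by n:
#: (D*_lo05, D*_hi05, D*_lo01, D*_hi01, F*_lo05, F*_hi05, F*_lo01, F*_hi01)
_FU_LI_CRIT: dict[int, tuple[float, ...]] = {
    6: (-1.531, 1.535, -1.531, 1.696, -1.659, 1.598, -1.659, 1.797),
    8: (-1.834, 1.407, -2.014, 1.587, -1.989, 1.516, -2.193, 1.776),
    12: (-2.098, 1.336, -2.528, 1.551, -2.288, 1.509, -2.727, 1.801),
    16: (-2.326, 1.320, -2.813, 1.563, -2.438, 1.526, -2.986, 1.833),
    24: (-2.412, 1.316, -3.272, 1.602, -2.446, 1.582, -3.247, 1.926),
    32: (-2.513, 1.317, -3.471, 1.636, -2.445, 1.611, -3.455, 2.018),
    48: (-2.338, 1.317, -3.435, 1.682, -2.351, 1.642, -3.362, 2.044),
    64: (-2.268, 1.311, -3.462, 1.709, -2.304, 1.648, -3.333, 2.125),
    80: (-2.494, 1.304, -3.338, 1.726, -2.285, 1.708, -3.258, 2.154),
    100: (-2.270, 1.292, -3.606, 1.738, -2.218, 1.703, -3.232, 2.166),
    150: (-2.131, 1.748, -3.100, 1.748, -2.147, 1.729, -2.961, 2.235),
    200: (-2.337, 1.747, -3.357, 1.747, -2.141, 1.748, -2.973, 2.275),
}


def _interp_crit(n: int) -> tuple[float, ...]:
    keys = sorted(_FU_LI_CRIT)
    if n <= keys[0]:
        return _FU_LI_CRIT[keys[0]]
    if n >= keys[-1]:
        return _FU_LI_CRIT[keys[-1]]
    lo = max(k for k in keys if k <= n)
    hi = min(k for k in keys if k >= n)
    if lo == hi:
        return _FU_LI_CRIT[lo]
    w = (n - lo) / (hi - lo)
    return tuple((1 - w) * a + w * b for a, b in zip(_FU_LI_CRIT[lo], _FU_LI_CRIT[hi]))


def fu_li_significance(dstar: float, fstar: float, n: int) -> tuple[str, str]:
    """Star flags ('', '*', '**') for D* and F* against the frozen
    simulation-derived two-sided critical values."""
    if not _FU_LI_CRIT:
        return "", ""
    d05lo, d05hi, d01lo, d01hi, f05lo, f05hi, f01lo, f01hi = _interp_crit(n)
    def flag(x, lo05, hi05, lo01, hi01):
        if not np.isfinite(x):
            return ""
        if x < lo01 or x > hi01:
            return "**"
        if x < lo05 or x > hi05:
            return "*"
        return ""
    return flag(dstar, d05lo, d05hi, d01lo, d01hi), flag(fstar, f05lo, f05hi, f01lo, f01hi)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

def _region_columns(panel: AlignedPanel, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a region's 1-based positions into (gap-free, gap-containing)."""
    is_gap = gap_columns(panel)
    mask = is_gap[positions - 1]
    return positions[~mask], positions[mask]


def summarize_regions(
    panel: AlignedPanel,
    model: GeneModel,
    vt: VariantTable | None = None,
    unions: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Diversity and neutrality summary per region, for the entire locus
    and for requested region unions (e.g. ``{"exons": ["exon1", "exon2",
    "exon3"]}``), with net-length pooling.

    Returns one row per scope with columns L_gross, L_net, S, eta_s, pi,
    theta_w, tajima_D, tajima_sig, fu_li_Dstar, Dstar_sig, fu_li_Fstar,
    Fstar_sig.  Statistics are NaN where S = 0.
    """
    if vt is None:
        from .variant_scan import call_variants
        vt = call_variants(panel, model)
    n = panel.n_samples
    scopes: list[tuple[str, np.ndarray]] = [(r.name, r.positions) for r in model.regions]
    scopes.append(("entire", np.concatenate([r.positions for r in model.regions])))
    for uname, members in (unions or {}).items():
        scopes.append((uname, np.concatenate([model.region(m).positions for m in members])))

    snps = vt.snps()
    rows = []
    for name, positions in scopes:
        posset = set(int(p) for p in positions)
        net_cols, gap_cols = _region_columns(panel, positions)
        L_gross, L_net = len(positions), len(net_cols)
        in_scope = [v for v in snps if v.position in posset]
        S = len(in_scope)
        eta_s = sum(1 for v in in_scope if v.site_class == "singleton")
        if S == 0:
            pi = theta = 0.0
            D = dstar = fstar = float("nan")
            sigD = sigDs = sigFs = ""
        else:
            pi = pairwise_pi(panel, net_cols)
            theta = watterson_theta(S, n, L_net)
            D = tajimas_d(pi, S, n, L_net)
            dstar, fstar = fu_li_star(S, eta_s, pi, n, L_net)
            sigD = significance_stars(tajima_d_pvalue(D, n))
            sigDs, sigFs = fu_li_significance(dstar, fstar, n)
        rows.append({
            "region": name, "L_gross": L_gross, "L_net": L_net,
            "S": S, "eta_s": eta_s, "pi": pi, "theta_w": theta,
            "tajima_D": D, "tajima_sig": sigD,
            "fu_li_Dstar": dstar, "Dstar_sig": sigDs,
            "fu_li_Fstar": fstar, "Fstar_sig": sigFs,
        })
        logger.info("region %-10s L_net=%d S=%d pi=%.5f theta=%.5f", name, L_net, S,
                    rows[-1]["pi"], rows[-1]["theta_w"])
    return pd.DataFrame(rows)


def table2_style(summary: pd.DataFrame, region_summary: pd.DataFrame) -> pd.DataFrame:
    """Wide, publication-style mirror of the summary: regions as columns,
    parameters as rows (variant bookkeeping on top, diversity below)."""
    merged = region_summary.merge(summary, on="region", how="right")
    out = pd.DataFrame({"Parameter": [
        "Total length (bp)", "Number of all sequence variants",
        "Number of nucleotide substitutions", "Number of indels",
        "Number of indel sites", "Average indel length",
        "pi", "theta_w", "Tajima's D", "Fu and Li's D*", "Fu and Li's F*",
    ]})
    for _, row in merged.iterrows():
        def fmt(x, nd=5):
            if x is None or (isinstance(x, float) and not np.isfinite(x)):
                return "NAN"
            return int(x) if nd == 0 else round(x, nd)
        out[row["region"]] = [
            row["L_gross"],
            fmt(row.get("n_variants"), 0), fmt(row.get("n_snps"), 0),
            fmt(row.get("n_indel_events"), 0), fmt(row.get("n_indel_sites"), 0),
            fmt(row.get("mean_indel_length"), 4),
            fmt(row["pi"]), fmt(row["theta_w"]),
            f'{fmt(row["tajima_D"])}{row["tajima_sig"]}',
            f'{fmt(row["fu_li_Dstar"])}{row["Dstar_sig"]}',
            f'{fmt(row["fu_li_Fstar"])}{row["Fstar_sig"]}',
        ]
    return out
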
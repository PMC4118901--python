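"""Linkage disequilibrium, LD decay and minimum recombination events.

Pairwise r-squared between biallelic SNPs on haploid haplotypes, Fisher's
exact significance, least-squares decay regression across five model
families (linear, loglinear, exponential, power and the Hill-Weir
drift-recombination expectation popularised for maize by Remington), and
the Hudson-Kaplan four-gamete lower bound on the number of recombination
events.

Indel events are excluded throughout: LD and the four-gamete test are
computed on SNPs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import logger
from .variant_scan import MISSING, Variant, VariantTable


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Long-format pairwise LD table over an ordered SNP list."""

    snp_ids: list[str]
    positions: list[int]
    pairs: pd.DataFrame  # site1, site2, pos1, pos2, distance, r2, p

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def significant(self, alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
        thresh = alpha / self.n_pairs if bonferroni else alpha
        return self.pairs[self.pairs["p"] < thresh]

    def matrix(self) -> pd.DataFrame:
        """Symmetric wide r2 matrix (diagonal 1)."""
        m = len(self.snp_ids)
        out = np.full((m, m), np.nan)
        np.fill_diagonal(out, 1.0)
        index = {s: i for i, s in enumerate(self.snp_ids)}
        for _, row in self.pairs.iterrows():
            i, j = index[row["site1"]], index[row["site2"]]
            out[i, j] = out[j, i] = row["r2"]
        return pd.DataFrame(out, index=self.snp_ids, columns=self.snp_ids)


def _biallelic_genotypes(v: Variant) -> np.ndarray:
    """0/1/NaN coding: 0 = major allele, 1 = minor; anything else missing."""
    g = np.full(len(v.genotypes), np.nan)
    g[v.genotypes == v.alleles[0]] = 0.0
    g[v.genotypes == v.alleles[1]] = 1.0
    return g


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype-frequency r2 between two 0/1 haploid site vectors
    (no missing values): r2 = D^2 / (pA pa pB pb)."""
    n = len(x)
    pA, pB = x.mean(), y.mean()
    pAB = np.mean(x * y)
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(D * D / denom)


def ld_matrix(vt: VariantTable, alpha: float = 0.05) -> LDMatrix:
    """All C(m,2) pairwise r2 and Fisher-exact p over the biallelic SNPs.

    Each pair uses its pairwise-complete sample subset; a pair whose
    subset leaves either site monomorphic is skipped with a log entry.
    """
    snps = [v for v in vt.snps() if v.is_biallelic()]
    snps = sorted(snps, key=lambda v: v.position)
    geno = {v.id: _biallelic_genotypes(v) for v in snps}
    rows = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            a, b = snps[i], snps[j]
            x, y = geno[a.id], geno[b.id]
            ok = ~np.isnan(x) & ~np.isnan(y)
            xs, ys = x[ok], y[ok]
            if len(np.unique(xs)) < 2 or len(np.unique(ys)) < 2:
                logger.info("LD pair %s/%s skipped: monomorphic in shared subset", a.id, b.id)
                continue
            r2 = r_squared(xs, ys)
            table = [[int(np.sum((xs == 0) & (ys == 0))), int(np.sum((xs == 0) & (ys == 1)))],
                     [int(np.sum((xs == 1) & (ys == 0))), int(np.sum((xs == 1) & (ys == 1)))]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({"site1": a.id, "site2": b.id, "pos1": a.position, "pos2": b.position,
                         "distance": abs(b.position - a.position), "r2": r2, "p": float(p)})
    pairs = pd.DataFrame(rows, columns=["site1", "site2", "pos1", "pos2", "distance", "r2", "p"])
    ld = LDMatrix([v.id for v in snps], [v.position for v in snps], pairs)
    logger.info("LD: %d SNPs, %d pairs, %d significant at %.2f",
                len(snps), ld.n_pairs, len(ld.significant(alpha)), alpha)
    return ld


# ---------------------------------------------------------------------------
# decay regression
# ---------------------------------------------------------------------------

def hill_weir_expectation(d: np.ndarray, c_per_bp: float, n: int) -> np.ndarray:
    """Drift-recombination expectation of r2 at distance d for sample size
    n, with C = c_per_bp * d the population recombination parameter."""
    C = c_per_bp * np.asarray(d, dtype=float)
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return term1 * term2


@dataclass
class ModelFit:
    name: str
    params: dict[str, float]
    r_squared: float
    distance_at: float | None  # smallest positive distance where fit crosses the target r2
    failed: bool = False


@dataclass
class DecayFit:
    fits: dict[str, ModelFit]
    selected: str  # maximal R^2 among successful fits
    target_r2: float = 0.1

    @property
    def best(self) -> ModelFit:
        return self.fits[self.selected]


def _coefficient_of_determination(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _smallest_positive_root(f, d_max: float) -> float | None:
    """Smallest positive d with f(d) = 0, scanned on (0, 100*d_max]."""
    grid = np.linspace(1e-9, 100 * d_max, 20000)
    vals = f(grid)
    sign = np.sign(vals)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if len(crossings) == 0:
        return None
    k = crossings[0]
    return float(optimize.brentq(f, grid[k], grid[k + 1]))


def fit_decay(ld: LDMatrix, n: int, target_r2: float = 0.1) -> DecayFit:
    """Least-squares decay fits of r2 against inter-site distance.

    Families: linear ``a + b*d``; loglinear ``a + b*ln d``; exponential
    ``a*exp(b*d)``; power ``a*d**b``; and the Hill-Weir expectation with
    the recombination scale ``c`` per bp as the free parameter
    (grid-seeded nonlinear least squares).  R^2 is computed on the
    original r2 scale for every family; the reported distance is the
    smallest positive solution of ``fit(d) = target_r2`` (None when the
    curve never reaches it).  The selected model maximises R^2 among the
    families that fitted.
    """
    d = ld.pairs["distance"].to_numpy(dtype=float)
    y = ld.pairs["r2"].to_numpy(dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 pairs to fit LD decay")
    d_max = float(d.max())
    fits: dict[str, ModelFit] = {}

    def add(name, params, predict):
        yhat = predict(d)
        root = _smallest_positive_root(lambda t: predict(t) - target_r2, d_max)
        fits[name] = ModelFit(name, params, _coefficient_of_determination(y, yhat), root)

    b, a = np.polyfit(d, y, 1)
    add("linear", {"a": float(a), "b": float(b)}, lambda t, a=a, b=b: a + b * t)

    bl, al = np.polyfit(np.log(d), y, 1)
    add("loglinear", {"a": float(al), "b": float(bl)}, lambda t, a=al, b=bl: a + b * np.log(t))

    pos = y > 0
    try:
        be0, ae0 = np.polyfit(d[pos], np.log(y[pos]), 1)
        (ae, be), _ = optimize.curve_fit(lambda t, a, b: a * np.exp(b * t), d, y,
                                         p0=[np.exp(ae0), be0], maxfev=20000)
        add("exponential", {"a": float(ae), "b": float(be)},
            lambda t, a=ae, b=be: a * np.exp(b * t))
    except (RuntimeError, TypeError, np.linalg.LinAlgError):
        fits["exponential"] = ModelFit("exponential", {}, -np.inf, None, failed=True)

    try:
        bp0, ap0 = np.polyfit(np.log(d[pos]), np.log(y[pos]), 1)
        (ap, bp), _ = optimize.curve_fit(lambda t, a, b: a * np.power(t, b), d, y,
                                         p0=[np.exp(ap0), bp0], maxfev=20000)
        add("power", {"a": float(ap), "b": float(bp)},
            lambda t, a=ap, b=bp: a * np.power(t, b))
    except (RuntimeError, TypeError, np.linalg.LinAlgError):
        fits["power"] = ModelFit("power", {}, -np.inf, None, failed=True)

    try:
        grid = np.logspace(-5, -1, 25)
        sse = [np.sum((y - hill_weir_expectation(d, c, n)) ** 2) for c in grid]
        c0 = grid[int(np.argmin(sse))]
        (c_hat,), _ = optimize.curve_fit(lambda t, c: hill_weir_expectation(t, c, n), d, y,
                                         p0=[c0], bounds=(0, np.inf), maxfev=20000)
        add("remington", {"c_per_bp": float(c_hat)},
            lambda t, c=c_hat: hill_weir_expectation(t, c, n))
    except (RuntimeError, TypeError, np.linalg.LinAlgError):
        fits["remington"] = ModelFit("remington", {}, -np.inf, None, failed=True)

    ok = {k: f for k, f in fits.items() if not f.failed}
    selected = max(ok, key=lambda k: ok[k].r_squared)
    logger.info("LD decay: selected %s (R2=%.4f), r2=%.2f reached at %s bp",
                selected, ok[selected].r_squared, target_r2, ok[selected].distance_at)
    return DecayFit(fits, selected, target_r2)


def decay_summary(fit: DecayFit) -> pd.DataFrame:
    rows = []
    for name, f in fit.fits.items():
        rows.append({
            "model": name,
            "params": ";".join(f"{k}={v:.6g}" for k, v in f.params.items()),
            "R2": f.r_squared if not f.failed else np.nan,
            f"distance_at_r2_{fit.target_r2}": f.distance_at,
            "selected": name == fit.selected,
            "failed": f.failed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# minimum recombination events (four-gamete test)
# ---------------------------------------------------------------------------

@dataclass
class RecombinationReport:
    rm: int
    intervals: list[tuple[int, int]]  # disjoint (left bp, right bp), sorted


def four_gamete_incompatible(x: np.ndarray, y: np.ndarray) -> bool:
    """True when two 0/1 site vectors exhibit all four gametes over their
    pairwise-complete subset."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    gametes = {(int(a), int(b)) for a, b in zip(x[ok], y[ok])}
    return len(gametes) == 4


def hudson_kaplan_rm(vt: VariantTable) -> RecombinationReport:
    """Hudson-Kaplan lower bound Rm on the number of recombination events.

    Every four-gamete-incompatible SNP pair defines an open interval
    between its positions; intervals containing another incompatible
    interval are discarded, and the remaining ones are scanned
    left-to-right keeping each interval disjoint from the last kept.  The
    number kept is Rm.
    """
    snps = sorted((v for v in vt.snps() if v.is_biallelic()), key=lambda v: v.position)
    geno = [_biallelic_genotypes(v) for v in snps]
    raw: list[tuple[int, int]] = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if four_gamete_incompatible(geno[i], geno[j]):
                raw.append((snps[i].position, snps[j].position))
    # keep only minimal intervals (containing no other incompatible interval)
    minimal = [iv for iv in raw
               if not any(o != iv and iv[0] <= o[0] and o[1] <= iv[1] for o in raw)]
    minimal.sort(key=lambda iv: iv[1])
    kept: list[tuple[int, int]] = []
    last_right = -np.inf
    for left, right in minimal:
        if left >= last_right:  # open intervals sharing an endpoint are disjoint
            kept.append((left, right))
            last_right = right
    kept.sort()
    logger.info("four-gamete test: %d incompatible pairs, Rm=%d", len(raw), len(kept))
    return RecombinationReport(len(kept), kept)
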
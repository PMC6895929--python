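"""Negative-binomial differential expression for count matrices.

The classic two-condition exact-test workflow: median-of-ratios size
factors, per-gene method-of-moments dispersion with a fitted
mean-dispersion trend (working dispersion = max of the two, the
conservative sharing rule), and a conditional NB exact test on the sum
of counts in each condition.  Calls use raw p < 0.05, fold change >= 2
and a minimum-read filter; Benjamini-Hochberg q-values are reported but
never gate the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess


# --------------------------------------------------------------------------
# size factors
# --------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes with any zero are excluded)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every library; a "
            "pseudo-reference over nonzero genes would be required")
    sub = mat[positive]
    log_geo = np.mean(np.log(sub), axis=1)
    sf = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# --------------------------------------------------------------------------
# dispersion
# --------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    per_gene: pd.Series       # raw method-of-moments alpha (floored at 0)
    trend: pd.Series          # trend value at each gene's mean
    working: pd.Series        # max(per_gene, trend)
    base_mean: pd.Series


def estimate_dispersions(counts: pd.DataFrame, size_factors: pd.Series,
                         groups: dict[str, list[str]]
                         ) -> DispersionEstimate:
    """Method-of-moments dispersion on common-scale counts.

    alpha_hat = max(0, (v - mean * xi) / mean^2) where v is the pooled
    within-group sample variance of the common-scale counts and xi the
    mean reciprocal size factor; the mean-dispersion trend is a lowess
    fit on log10 mean, and the working value is the conservative
    per-gene/trend maximum.
    """
    sizes = [len(libs) for libs in groups.values()]
    if max(sizes) < 2:
        raise ValueError("dispersion estimation requires replication "
                         "in at least one group")
    q = counts / size_factors
    xi = float(np.mean(1.0 / size_factors.to_numpy()))
    base_mean = q.mean(axis=1)

    ss = pd.Series(0.0, index=counts.index)
    df_total = 0
    for libs in groups.values():
        if len(libs) < 2:
            continue
        sub = q[libs]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        df_total += len(libs) - 1
    v = ss / df_total

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - base_mean * xi) / base_mean ** 2
    per_gene = raw.clip(lower=0.0).fillna(0.0)

    ok = base_mean > 0
    if ok.sum() >= 10:
        fit = lowess(per_gene[ok].to_numpy(),
                     np.log10(base_mean[ok].to_numpy()),
                     frac=0.5, return_sorted=True)
        xs, ys = fit[:, 0], np.maximum(fit[:, 1], 0.0)
        trend_vals = np.interp(np.log10(base_mean[ok].to_numpy()), xs, ys)
        trend = pd.Series(0.0, index=counts.index)
        trend[ok] = trend_vals
    else:
        trend = pd.Series(float(per_gene[ok].median()) if ok.any() else 0.0,
                          index=counts.index)
    working = pd.concat([per_gene, trend], axis=1).max(axis=1)
    return DispersionEstimate(per_gene, trend, working, base_mean)


# --------------------------------------------------------------------------
# exact test
# --------------------------------------------------------------------------

def _nb_pmf_vector(ks: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB pmf with the given mean/variance; Poisson when var <= mean."""
    if mean <= 0:
        return np.where(ks == 0, 1.0, 0.0)
    if var <= mean * (1 + 1e-12):
        return sps.poisson.pmf(ks, mean)
    p = mean / var
    r = mean * mean / (var - mean)
    return sps.nbinom.pmf(ks, r, p)


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray,
                  sf_a: np.ndarray, sf_b: np.ndarray,
                  dispersion: float) -> float:
    """Two-sided conditional exact test on the condition count sums.

    Conditional on K = K_A + K_B, sums the probabilities of all splits
    (a, K - a) no more likely than the observed one under fitted NB laws
    for each condition's sum (variance mu + alpha*mu^2 propagated through
    the size factors).
    """
    if not np.isfinite(dispersion) or dispersion < 0:
        raise ValueError("dispersion must be finite and >= 0")
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be >= 0")
    ka, kb = counts_a.sum(), counts_b.sum()
    K = int(round(ka + kb))
    if K == 0:
        return 1.0
    all_counts = np.concatenate([counts_a, counts_b])
    all_sf = np.concatenate([sf_a, sf_b])
    q0 = float(np.sum(all_counts) / np.sum(all_sf))

    mu_a = q0 * np.sum(sf_a)
    mu_b = q0 * np.sum(sf_b)
    var_a = mu_a + dispersion * q0 * q0 * np.sum(sf_a ** 2)
    var_b = mu_b + dispersion * q0 * q0 * np.sum(sf_b ** 2)

    ks = np.arange(K + 1)
    pa = _nb_pmf_vector(ks, mu_a, var_a)
    pb = _nb_pmf_vector(ks[::-1], mu_b, var_b)
    joint = pa * pb
    total = joint.sum()
    if total <= 0:
        return 1.0
    obs = joint[int(round(ka))]
    p = joint[joint <= obs * (1 + 1e-10)].sum() / total
    return float(min(1.0, max(p, np.nextafter(0, 1))))


# --------------------------------------------------------------------------
# DE table and calls
# --------------------------------------------------------------------------

def run_de(counts: pd.DataFrame, conditions: dict[str, str],
           condition_a: str, condition_b: str,
           min_reads: int = 3) -> pd.DataFrame:
    """Full DE table for condition_b vs condition_a.

    Genes whose maximum raw count across libraries is below `min_reads`
    are excluded before testing.  Fold change is baseMeanB / baseMeanA
    on common-scale means, with a +0.5 pseudo-count applied to both
    means when either is zero.
    """
    libs_a = [c for c in counts.columns if conditions.get(c) == condition_a]
    libs_b = [c for c in counts.columns if conditions.get(c) == condition_b]
    if not libs_a or not libs_b:
        raise ValueError("both conditions need at least one library")

    keep = counts.max(axis=1) >= min_reads
    sub = counts[keep]
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(sub, sf,
                                {condition_a: libs_a, condition_b: libs_b})
    q = sub / sf
    mean_a = q[libs_a].mean(axis=1)
    mean_b = q[libs_b].mean(axis=1)

    sfa = sf[libs_a].to_numpy()
    sfb = sf[libs_b].to_numpy()
    pvals = np.empty(len(sub))
    for i, gene in enumerate(sub.index):
        pvals[i] = nb_exact_test(sub.loc[gene, libs_a].to_numpy(),
                                 sub.loc[gene, libs_b].to_numpy(),
                                 sfa, sfb, float(disp.working[gene]))

    ma, mb = mean_a.to_numpy(), mean_b.to_numpy()
    zero = (ma == 0) | (mb == 0)
    fc = np.where(zero, (mb + 0.5) / (ma + 0.5),
                  np.divide(mb, ma, out=np.ones_like(mb), where=ma > 0))
    padj = sps.false_discovery_control(pvals, method="bh") if len(pvals) \
        else np.array([])
    out = pd.DataFrame({
        "baseMeanA": ma, "baseMeanB": mb,
        "foldChange": fc, "log2FoldChange": np.log2(fc),
        "pval": pvals, "padj": padj,
        "maxRawCount": sub.max(axis=1).to_numpy(),
        "dispersion": disp.working[sub.index].to_numpy(),
    }, index=sub.index)
    return out.sort_values(["pval", "foldChange"])


def call_de(results: pd.DataFrame, p_threshold: float = 0.05,
            fc_threshold: float = 2.0, min_reads: int = 3
            ) -> tuple[list[str], list[str]]:
    """Up/down gene lists at the standard thresholds.

    A gene is called iff p < p_threshold, fold change >= fc_threshold
    (up) or <= 1/fc_threshold (down), and its max raw count passes the
    minimum-read gate.  Lists are ordered by (p, id).
    """
    if results.empty:
        raise ValueError("empty results table")
    ok = ((results["pval"] < p_threshold)
          & (results["maxRawCount"] >= min_reads))
    up = results[ok & (results["foldChange"] >= fc_threshold)]
    down = results[ok & (results["foldChange"] <= 1.0 / fc_threshold)]
    up = up.assign(_id=up.index).sort_values(["pval", "_id"])
    down = down.assign(_id=down.index).sort_values(["pval", "_id"])
    return list(up.index), list(down.index)


def replicate_correlation(counts: pd.DataFrame,
                          conditions: dict[str, str]) -> pd.DataFrame:
    """Pearson r for every within-condition replicate pair.

    A zero-variance library yields r = NaN with `degenerate` flagged,
    never a silent zero.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    rows = []
    bycond: dict[str, list[str]] = {}
    for lib in counts.columns:
        bycond.setdefault(conditions.get(lib, "?"), []).append(lib)
    for cond, libs in bycond.items():
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                x = counts[libs[i]].to_numpy(dtype=float)
                y = counts[libs[j]].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    rows.append((cond, libs[i], libs[j], np.nan, True))
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    rows.append((cond, libs[i], libs[j], r, False))
    return pd.DataFrame(rows, columns=["condition", "library_a",
                                       "library_b", "pearson_r",
                                       "degenerate"])
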
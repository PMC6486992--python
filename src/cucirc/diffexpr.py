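"""Differential expression of circRNAs between conditions.

The caller tests, per circRNA, whether the pooled junction-read count is
split between the two conditions in proportion to the pooled mapped library
sizes (an exact two-sided binomial test), reports the fold change on mean
SRPBM with a small pseudocount, adjusts p-values by Benjamini-Hochberg, and
applies the cut-off |log2FC| > 1 (strict) and FDR <= 0.05 (non-strict).
An empirical-Bayes negative-binomial model is deliberately not replicated;
externally computed p-values can be substituted through ``call_de``.

``global_shift`` compares whole log2(SRPBM+1) abundance distributions
between conditions with a two-sided Wilcoxon rank-sum test (exact for
combined n <= 20 without ties, normal approximation with continuity
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "de_test",
    "bh_adjust",
    "call_de",
    "global_shift",
    "de_report",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_LFC_CUTOFF",
    "DEFAULT_FDR_CUTOFF",
]

DEFAULT_PSEUDOCOUNT = 0.01  # SRPBM units
DEFAULT_LFC_CUTOFF = 1.0
DEFAULT_FDR_CUTOFF = 0.05


def estimate_dispersion(
    raw: pd.DataFrame,
    library_sizes: Mapping[str, int],
    groups: Sequence[Sequence[str]],
    min_mean: float = 5.0,
) -> float:
    """Common negative-binomial dispersion from within-group replicate scatter.

    Counts are first rescaled to the mean library size; per circ and group,
    the moment identity E[s^2 - m] = theta m^2 identifies the quadratic
    overdispersion theta (var = mu + theta mu^2).  The pooled estimate is the
    ratio of sums sum(s^2 - m) / sum(m^2) over circs with mean count >=
    ``min_mean`` (a ratio of unbiased numerators, stable even with two
    replicates), clipped at 0.  Returns 0 when no group has replication or
    no circ is expressed high enough.
    """
    samples = [s for g in groups for s in g]
    mean_lib = np.mean([library_sizes[s] for s in samples])
    scaled = raw[samples].astype(float).copy()
    for s in samples:
        scaled[s] = scaled[s] * (mean_lib / library_sizes[s])

    num = 0.0
    den = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        block = scaled[list(g)]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        ok = m >= min_mean
        if ok.any():
            num += float((v[ok] - m[ok]).sum())
            den += float((m[ok] ** 2).sum())
    if den <= 0:
        return 0.0
    return float(max(0.0, num / den))


def de_test(
    raw: pd.DataFrame,
    srpbm: pd.DataFrame,
    library_sizes: Mapping[str, int],
    treated: Sequence[str],
    control: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dispersion: float | str | None = "auto",
) -> pd.DataFrame:
    """Per-circ log2 fold change (treated vs control) and test p-value.

    The test compares pooled junction counts against pooled mapped library
    sizes across the two conditions.  With ``dispersion=0`` it is the
    two-sided exact binomial test of the pooled proportion.  Junction counts
    of replicated libraries are biologically overdispersed, which makes the
    plain binomial badly anti-conservative, so by default ("auto") a common
    negative-binomial dispersion theta is estimated from within-condition
    replicate scatter and a Wald test on the log count-rate ratio is used,
    with variance 1/(k_t + 1/2) + 1/(k_c + 1/2) + theta (1/n_t + 1/n_c)
    (counting noise plus the biological variance floor of the replicate
    design).  The exact test is used whenever the estimated dispersion is 0.

    The fold change is log2((mean SRPBM_t + c) / (mean SRPBM_c + c)).
    """
    treated, control = list(treated), list(control)
    lib_t = float(sum(library_sizes[s] for s in treated))
    lib_c = float(sum(library_sizes[s] for s in control))
    if lib_t <= 0 or lib_c <= 0:
        raise ValueError("library sizes must be positive in both groups")
    p_null = lib_t / (lib_t + lib_c)

    if dispersion == "auto":
        theta = estimate_dispersion(raw, library_sizes, [treated, control])
    elif dispersion is None:
        theta = 0.0
    else:
        theta = float(dispersion)

    k_t = raw[treated].sum(axis=1).to_numpy(dtype=float)
    k_c = raw[control].sum(axis=1).to_numpy(dtype=float)
    n = k_t + k_c
    pvals = np.ones(len(n))
    if theta == 0.0:
        for i in range(len(n)):
            if n[i] > 0:
                pvals[i] = sps.binomtest(int(k_t[i]), int(n[i]), p_null).pvalue
    else:
        rate_t = (k_t + 0.5) / lib_t
        rate_c = (k_c + 0.5) / lib_c
        var = (
            1.0 / (k_t + 0.5)
            + 1.0 / (k_c + 0.5)
            + theta * (1.0 / len(treated) + 1.0 / len(control))
        )
        z = np.log(rate_t / rate_c) / np.sqrt(var)
        pvals = np.where(n > 0, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
        pvals = np.minimum(pvals, 1.0)

    mean_t = srpbm[treated].mean(axis=1).to_numpy()
    mean_c = srpbm[control].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    return pd.DataFrame({"log2fc": log2fc, "p_value": pvals}, index=raw.index)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> pd.DataFrame:
    """Add BH-adjusted FDR and up/down/ns calls at the cut-offs.

    A circ is "up" iff log2fc > lfc_cutoff (strict) and fdr <= fdr_cutoff
    (non-strict); "down" symmetrically; otherwise "ns".
    """
    out = results.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    call = np.where(
        (out["log2fc"] > lfc_cutoff) & (out["fdr"] <= fdr_cutoff),
        "up",
        np.where(
            (out["log2fc"] < -lfc_cutoff) & (out["fdr"] <= fdr_cutoff), "down", "ns"
        ),
    )
    out["call"] = call
    return out


def global_shift(
    group1: Sequence[float], group2: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two abundance distributions.

    Exact null distribution for combined n <= 20 without ties; otherwise the
    normal approximation with continuity (and tie) correction.  Returns the
    Mann-Whitney U statistic of group1 and the two-sided p-value.
    """
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return u, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def de_report(calls_per_tissue: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total counts per tissue plus the union over tissues.

    Per-tissue totals are up + down; the union row counts distinct circ_ids
    called in any tissue once.
    """
    rows = []
    union: set = set()
    for tissue in calls_per_tissue:
        df = calls_per_tissue[tissue]
        up = int((df["call"] == "up").sum())
        down = int((df["call"] == "down").sum())
        rows.append({"tissue": tissue, "up": up, "down": down, "total": up + down})
        union |= set(df.index[df["call"] != "ns"])
    rows.append({"tissue": "union", "up": None, "down": None, "total": len(union)})
    return pd.DataFrame(rows, columns=["tissue", "up", "down", "total"])
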
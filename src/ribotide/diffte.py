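"""Differential translation-efficiency statistics.

The core quantities, per gene, computed on group means of CPM-normalized
counts over two conditions (WT and MUT) with paired replicates:

* signed fold changes of mRNA and RPF abundance: a ratio r >= 1 is reported
  as r, a ratio r < 1 as -1/r (so a 4-fold reduction prints as -4.0);
* translation efficiency TE = RPF / mRNA and its fold change, which on
  group means equals the ratio of the RPF and mRNA fold changes;
* the delta-method SD of a ratio of paired replicate means, including the
  covariance correction:

      SD = (m_k/m_w) * sqrt((s_k/m_k)^2 + (s_w/m_w)^2 - 2*cov/(m_k*m_w))

  where m, s are per-condition means and sample SDs and cov is the paired
  sample covariance (replicates paired by index, i.e. by harvest batch);
* Welch t-tests on log2 CPM with Benjamini-Hochberg FDR adjustment, and
  thresholded up/down/unchanged classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

METRICS = ("mrna", "rpf", "te")


# ---------------------------------------------------------------------------
# signed-fold arithmetic


def signed_fold(ratio: float) -> float:
    """Map a positive ratio onto the signed-fold convention (|fold| >= 1)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return float(ratio) if ratio >= 1 else -1.0 / float(ratio)


def signed_to_ratio(fold: float) -> float:
    """Inverse of :func:`signed_fold`."""
    if abs(fold) < 1:
        raise ValueError(f"|signed fold| must be >= 1, got {fold}")
    return float(fold) if fold >= 1 else -1.0 / float(fold)


def fold_change(mean_mut: float, mean_wt: float) -> float:
    """Signed fold of mutant over wild-type group means (NaN if undefined)."""
    if mean_mut <= 0 or mean_wt <= 0 or np.isnan(mean_mut) or np.isnan(mean_wt):
        return float("nan")
    return signed_fold(mean_mut / mean_wt)


def translation_efficiency(rpf_mean: float, mrna_mean: float) -> float:
    """TE = RPF / mRNA on matching group means (NaN when mRNA is zero)."""
    if mrna_mean <= 0 or np.isnan(mrna_mean):
        return float("nan")
    return float(rpf_mean) / float(mrna_mean)


def te_fold_change(fc_rpf: float, fc_mrna: float) -> float:
    """Signed TE fold from the RPF and mRNA signed folds.

    Algebraically equal to signed_fold((RPF_MUT/RPF_WT)/(mRNA_MUT/mRNA_WT))
    on group means.
    """
    if np.isnan(fc_rpf) or np.isnan(fc_mrna):
        return float("nan")
    return signed_fold(signed_to_ratio(fc_rpf) / signed_to_ratio(fc_mrna))


def round_signed_fold(fold: float, decimals: int = 1) -> float:
    """Round the magnitude, keep the sign (the tables' printing rule)."""
    return float(np.sign(fold) * np.round(abs(fold), decimals))


# ---------------------------------------------------------------------------
# SD of a ratio with paired covariance


@dataclass(frozen=True)
class RatioSD:
    value: float
    radicand_clipped: bool = False


def sd_of_ratio(values_mut, values_wt) -> RatioSD:
    """Delta-method SD of the ratio of paired replicate means.

    Replicates are paired by index (same harvest batch). A slightly negative
    radicand - possible when strong covariance meets sampling noise - is
    clipped to zero and flagged.
    """
    k = np.asarray(values_mut, dtype=float)
    w = np.asarray(values_wt, dtype=float)
    if k.shape != w.shape or k.ndim != 1 or k.size < 2:
        raise ValueError("need equal-length replicate vectors with n >= 2")
    m_k, m_w = k.mean(), w.mean()
    if m_k == 0 or m_w == 0:
        return RatioSD(float("nan"))
    s_k, s_w = k.std(ddof=1), w.std(ddof=1)
    cov = float(np.cov(k, w, ddof=1)[0, 1])
    radicand = (s_k / m_k) ** 2 + (s_w / m_w) ** 2 - 2 * cov / (m_k * m_w)
    if radicand < 0:
        return RatioSD(0.0, radicand_clipped=True)
    return RatioSD(float((m_k / m_w) * np.sqrt(radicand)))


def sd_on_fold_scale(ratio: float, sd_ratio: float) -> float:
    """Transfer an SD from the ratio scale to the printed signed-fold scale.

    For increases the fold is the ratio itself; for reductions the fold
    magnitude is 1/r, whose delta-method SD is sd_ratio / r^2.
    """
    if np.isnan(ratio) or np.isnan(sd_ratio):
        return float("nan")
    return float(sd_ratio) if ratio >= 1 else float(sd_ratio) / ratio**2


# ---------------------------------------------------------------------------
# tests and FDR


def welch_log2_test(values_a, values_b, pseudocount: float = 0.5) -> float:
    """Two-sided Welch t-test on log2(value + pseudocount) per replicate."""
    a = np.log2(np.asarray(values_a, dtype=float) + pseudocount)
    b = np.log2(np.asarray(values_b, dtype=float) + pseudocount)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# per-gene table and summaries


def _group_columns(samples: pd.DataFrame, condition: str) -> list[str]:
    sub = samples[samples["condition"] == condition]
    return list(sub.sort_values("replicate").index)


def compute_gene_stats(
    cpm_rpf: pd.DataFrame,
    cpm_rna: pd.DataFrame,
    samples_rpf: pd.DataFrame,
    samples_rna: pd.DataFrame,
    fc_cutoff: float = 2.0,
    q_cutoff: float = 0.05,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene differential table plus genome-wide summary.

    ``cpm_*`` are genes x samples CPM frames; ``samples_*`` index the columns
    with ``condition`` (WT/MUT) and ``replicate`` labels. RPF and RNA
    replicates are paired by (condition, replicate index).
    """
    genes = cpm_rpf.index
    if not genes.equals(cpm_rna.index):
        raise ValueError("RPF and RNA matrices must share the same gene index")

    cols = {}
    for assay, cpm, samples in (
        ("rpf", cpm_rpf, samples_rpf),
        ("mrna", cpm_rna, samples_rna),
    ):
        for cond in ("WT", "MUT"):
            cols[(assay, cond)] = cpm[_group_columns(samples, cond)].to_numpy()

    # per-replicate TE, paired by replicate index within condition
    te = {
        cond: (cols[("rpf", cond)] + pseudocount)
        / (cols[("mrna", cond)] + pseudocount)
        for cond in ("WT", "MUT")
    }

    out = pd.DataFrame(index=genes)
    means = {}
    for metric, arrays in (
        ("mrna", (cols[("mrna", "WT")], cols[("mrna", "MUT")])),
        ("rpf", (cols[("rpf", "WT")], cols[("rpf", "MUT")])),
        ("te", (te["WT"], te["MUT"])),
    ):
        wt, mut = arrays
        means[metric] = (wt.mean(axis=1), mut.mean(axis=1))

    out["mean_mRNA_WT"], out["mean_mRNA_MUT"] = means["mrna"][0], means["mrna"][1]
    out["mean_RPF_WT"], out["mean_RPF_MUT"] = means["rpf"][0], means["rpf"][1]
    out["te_WT"] = [
        translation_efficiency(r, m)
        for r, m in zip(out["mean_RPF_WT"], out["mean_mRNA_WT"])
    ]
    out["te_MUT"] = [
        translation_efficiency(r, m)
        for r, m in zip(out["mean_RPF_MUT"], out["mean_mRNA_MUT"])
    ]

    out["fc_mrna"] = [
        fold_change(m, w) for w, m in zip(*means["mrna"])
    ]
    out["fc_rpf"] = [
        fold_change(m, w) for w, m in zip(*means["rpf"])
    ]
    out["fc_te"] = [
        te_fold_change(fr, fm)
        for fr, fm in zip(out["fc_rpf"], out["fc_mrna"])
    ]

    # SDs of the ratios, expressed on the printed fold scale
    for metric, (wt, mut) in (
        ("mrna", (cols[("mrna", "WT")], cols[("mrna", "MUT")])),
        ("rpf", (cols[("rpf", "WT")], cols[("rpf", "MUT")])),
        ("te", (te["WT"], te["MUT"])),
    ):
        sds = []
        for i in range(len(genes)):
            res = sd_of_ratio(mut[i], wt[i])
            m_w, m_k = wt[i].mean(), mut[i].mean()
            ratio = m_k / m_w if m_w > 0 else float("nan")
            sds.append(sd_on_fold_scale(ratio, res.value))
        out[f"sd_fc_{metric}"] = sds

    # Welch tests on log2 values, BH within each metric
    for metric, (wt, mut) in (
        ("mrna", (cols[("mrna", "WT")], cols[("mrna", "MUT")])),
        ("rpf", (cols[("rpf", "WT")], cols[("rpf", "MUT")])),
        ("te", (te["WT"], te["MUT"])),
    ):
        pvals = np.array(
            [welch_log2_test(mut[i], wt[i], pseudocount)
             for i in range(len(genes))]
        )
        out[f"p_{metric}"] = pvals
        out[f"q_{metric}"] = bh_adjust(pvals)

    for metric in METRICS:
        out[f"class_{metric}"] = classify(
            out[f"fc_{metric}"], out[f"q_{metric}"], fc_cutoff, q_cutoff
        )

    summary = summarize(out, fc_cutoff, q_cutoff)
    return out, summary


def classify(fc: pd.Series, q: pd.Series, fc_cutoff: float = 2.0,
             q_cutoff: float = 0.05) -> pd.Series:
    """Label genes up/down/unchanged by |signed fold| and FDR cutoffs."""
    labels = pd.Series("unchanged", index=fc.index, dtype=object)
    sig = (q < q_cutoff) & fc.notna()
    labels[sig & (fc >= fc_cutoff)] = "up"
    labels[sig & (fc <= -fc_cutoff)] = "down"
    return labels


def summarize(stats_table: pd.DataFrame, fc_cutoff: float = 2.0,
              q_cutoff: float = 0.05) -> dict:
    """Affected-gene counts, the RPF-vs-mRNA log2 fold R^2, plot tables."""
    ok = (
        stats_table["fc_mrna"].notna() & stats_table["fc_rpf"].notna()
    )
    log2_mrna = np.log2(
        [signed_to_ratio(f) for f in stats_table.loc[ok, "fc_mrna"]]
    )
    log2_rpf = np.log2(
        [signed_to_ratio(f) for f in stats_table.loc[ok, "fc_rpf"]]
    )
    if len(log2_mrna) >= 2 and np.std(log2_mrna) > 0 and np.std(log2_rpf) > 0:
        r = stats.pearsonr(log2_mrna, log2_rpf).statistic
        r_squared = float(r**2)
    else:
        r_squared = float("nan")

    summary: dict = {
        "n_genes": int(len(stats_table)),
        "fc_cutoff": fc_cutoff,
        "q_cutoff": q_cutoff,
        "r_squared_rpf_vs_mrna": r_squared,
    }
    for metric in METRICS:
        counts = stats_table[f"class_{metric}"].value_counts()
        summary[f"n_up_{metric}"] = int(counts.get("up", 0))
        summary[f"n_down_{metric}"] = int(counts.get("down", 0))
    return summary


def scatter_table(stats_table: pd.DataFrame) -> pd.DataFrame:
    """log2 mRNA vs RPF fold coordinates (the fold-correlation scatter)."""
    ok = stats_table["fc_mrna"].notna() & stats_table["fc_rpf"].notna()
    sub = stats_table.loc[ok]
    return pd.DataFrame(
        {
            "log2_fc_mrna": [np.log2(signed_to_ratio(f)) for f in sub["fc_mrna"]],
            "log2_fc_rpf": [np.log2(signed_to_ratio(f)) for f in sub["fc_rpf"]],
        },
        index=sub.index,
    )


def volcano_table(stats_table: pd.DataFrame, metric: str = "te") -> pd.DataFrame:
    """log2 fold vs -log10 q coordinates for one metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    ok = stats_table[f"fc_{metric}"].notna()
    sub = stats_table.loc[ok]
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(sub[f"q_{metric}"].to_numpy())
    return pd.DataFrame(
        {
            f"log2_fc_{metric}": [
                np.log2(signed_to_ratio(f)) for f in sub[f"fc_{metric}"]
            ],
            "neg_log10_q": neglog_q,
        },
        index=sub.index,
    )
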
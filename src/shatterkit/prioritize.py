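"""Candidate-gene prioritization over the minimally amplified region.

Three screens feed the candidate table: a single-cell differential-expression
rank-sum screen restricted to the MAR gene panel, an integration rule over
precomputed bulk DE and differential-accessibility (DA) peak tables
(candidate = MAR gene, DE up, and a significant promoter DA peak), and an
allele-specific-expression skew test against the copy-number-implied allelic
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PROMOTER_WINDOW = (-2000, 500)  # around the TSS, when peaks lack a flag


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize (cells x genes) and log2(1 + x) transform."""
    totals = counts.sum(axis=1).replace(0, 1)
    return np.log2(1.0 + counts.div(totals, axis=0) * scale)


def sc_de_screen(count_matrix: pd.DataFrame,
                 group_labels: Sequence,
                 gene_subset: Sequence[str],
                 alpha: float = 0.05,
                 case_label="amp") -> pd.DataFrame:
    """Per-gene two-sided rank-sum screen of case vs control cells.

    ``count_matrix`` holds log-normalized expression (cells x genes);
    p-values are Benjamini-Hochberg adjusted across ``gene_subset``.  A gene
    is called up iff adjusted p < ``alpha`` and its mean is higher in the
    case group.  Genes absent from the matrix are reported, not fatal.
    """
    labels = np.asarray(group_labels)
    case = labels == case_label
    if case.all() or not case.any():
        raise ValueError("need two non-empty groups")
    rows = []
    for gene in gene_subset:
        if gene not in count_matrix.columns:
            rows.append({"gene": gene, "log2_fc": np.nan, "p": np.nan,
                         "expressing_frac_case": np.nan,
                         "expressing_frac_control": np.nan,
                         "missing": True})
            continue
        x = count_matrix[gene].to_numpy()
        a, b = x[case], x[~case]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"gene": gene,
                     "log2_fc": float(a.mean() - b.mean()),
                     "p": p,
                     "expressing_frac_case": float((a > 0).mean()),
                     "expressing_frac_control": float((b > 0).mean()),
                     "missing": False})
    out = pd.DataFrame(rows)
    present = ~out["missing"]
    out["p_adj"] = np.nan
    if present.any():
        out.loc[present, "p_adj"] = multipletests(
            out.loc[present, "p"], method="fdr_bh")[1]
    out["up"] = present & (out["p_adj"] < alpha) & (out["log2_fc"] > 0)
    return out


@dataclass(frozen=True)
class IntegrationThresholds:
    de_p_adj: float = 0.05
    da_p_adj: float = 0.05
    de_log2_fc_min: float = 0.0


def integrate_de_da(de_table: pd.DataFrame,
                    da_table: pd.DataFrame,
                    mar_genes: Sequence[str],
                    thresholds: IntegrationThresholds | None = None,
                    ) -> pd.DataFrame:
    """Flag MAR genes that are bulk-DE up *and* have a significant promoter
    DA peak; rank candidates by promoter-peak then DE fold change.

    ``de_table`` needs columns gene / log2_fc / p_adj; ``da_table`` needs
    gene / is_promoter / log2_fc / p_adj.  The output has one row per MAR
    gene with the individual evidence flags, so near-misses (e.g. DE-up
    genes with only gene-body peaks) remain visible.
    """
    t = thresholds or IntegrationThresholds()
    mar_genes = list(mar_genes)
    if not mar_genes:
        raise ValueError("MAR gene list is empty")
    de = de_table.set_index("gene")
    rows = []
    for gene in mar_genes:
        de_up = bool(
            gene in de.index
            and de.loc[gene, "p_adj"] < t.de_p_adj
            and de.loc[gene, "log2_fc"] > t.de_log2_fc_min)
        peaks = da_table[da_table["gene"] == gene]
        prom = peaks[(peaks["is_promoter"].astype(bool))
                     & (peaks["p_adj"] < t.da_p_adj)]
        has_prom = bool(len(prom))
        rows.append({
            "gene": gene,
            "in_mar": True,
            "bulk_de_up": de_up,
            "has_da_promoter": has_prom,
            "candidate": de_up and has_prom,
            "promoter_log2_fc": float(prom["log2_fc"].max()) if has_prom else np.nan,
            "de_log2_fc": float(de.loc[gene, "log2_fc"]) if gene in de.index else np.nan,
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["candidate", "promoter_log2_fc", "de_log2_fc", "gene"],
        ascending=[False, False, False, True], na_position="last")
    out["priority_rank"] = np.where(out["candidate"],
                                    np.arange(1, len(out) + 1), 0)
    out.loc[~out["candidate"], "priority_rank"] = pd.NA
    return out.reset_index(drop=True)


def assign_promoter_flags(da_table: pd.DataFrame,
                          tss: Mapping[str, tuple[str, int]],
                          window: tuple[int, int] = PROMOTER_WINDOW
                          ) -> pd.DataFrame:
    """Derive ``is_promoter`` from peak coordinates and a gene->TSS map."""
    lo, hi = window
    flags = []
    for row in da_table.itertuples(index=False):
        chrom_tss = tss.get(row.gene)
        if chrom_tss is None:
            flags.append(0)
            continue
        chrom, pos = chrom_tss
        flags.append(int(row.chrom == chrom
                         and row.start < pos + hi and row.end > pos + lo))
    out = da_table.copy()
    out["is_promoter"] = flags
    return out


# ---------------------------------------------------------------------------
# allele-specific expression

def _stouffer(pvals: np.ndarray, signs: np.ndarray) -> float:
    """Combine two-sided p-values with directions into one two-sided p."""
    z = stats.norm.isf(np.clip(pvals, 1e-300, 1.0) / 2.0) * signs
    zc = z.sum() / np.sqrt(len(z))
    return float(2.0 * stats.norm.sf(abs(zc)))


def ase_test(snp_read_counts: pd.DataFrame,
             total_cn: float | None = None,
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene allelic-skew test of amplified-allele read fractions.

    ``snp_read_counts`` needs columns gene / amp_reads / total_reads (and
    optionally per-row total_cn overriding the argument).  Per SNP, an exact
    binomial test against 0.5 detects skew and one against the dosage
    expectation f = (CN-1)/CN checks copy-number consistency; SNP p-values
    are combined per gene by equal-weight Stouffer.  A gene is skewed iff
    the combined p(vs 0.5) < ``alpha`` with bias toward the amplified allele.
    """
    df = snp_read_counts.copy()
    if "total_cn" not in df.columns:
        if total_cn is None:
            raise ValueError("total_cn must be given as column or argument")
        df["total_cn"] = total_cn
    if (df["total_cn"] < 2).any():
        raise ValueError("total_cn must be >= 2")
    df = df[df["total_reads"] > 0]
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        p_bal, p_dos, signs_bal, signs_dos = [], [], [], []
        fracs = []
        for row in grp.itertuples(index=False):
            f_exp = (row.total_cn - 1.0) / row.total_cn
            p_bal.append(stats.binomtest(int(row.amp_reads),
                                         int(row.total_reads), 0.5).pvalue)
            p_dos.append(stats.binomtest(int(row.amp_reads),
                                         int(row.total_reads), f_exp).pvalue)
            frac = row.amp_reads / row.total_reads
            fracs.append(frac)
            signs_bal.append(1.0 if frac >= 0.5 else -1.0)
            signs_dos.append(1.0 if frac >= f_exp else -1.0)
        if len(p_bal) == 1:
            p_skew, p_cn = float(p_bal[0]), float(p_dos[0])
        else:
            p_skew = _stouffer(np.array(p_bal), np.array(signs_bal))
            p_cn = _stouffer(np.array(p_dos), np.array(signs_dos))
        mean_frac = float(np.mean(fracs))
        direction = ("amplified" if mean_frac > 0.5
                     else "other" if mean_frac < 0.5 else "balanced")
        rows.append({"gene": gene, "n_snps": len(grp),
                     "mean_amp_fraction": mean_frac,
                     "p_skew": p_skew,
                     "p_vs_dosage": p_cn,
                     "skew_direction": direction,
                     "skewed": bool(p_skew < alpha and mean_frac > 0.5),
                     "consistent_with_cn": bool(p_cn >= alpha)})
    return pd.DataFrame(rows)
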
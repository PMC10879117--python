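"""Endogenous-factor annotation of target sites.

Quantifies transcriptional and epigenetic context at each guide target:
peak overlap (Pol II, CTCF, DHS, histone marks, CREs), gene expression,
and per-base DNA methylation; plus the factor-vs-efficiency statistics
(confounder-adjusted regression, promoted-motif ratio).

Conventions: BED half-open intervals, >= 1 bp overlap counts as a hit.
H3K27ac is queried over a widened interval (protospacer +/- flank,
default 65 bp giving the 150-bp window; 500 bp gives the 1020-bp
window) because acetylation domains extend well beyond a nucleosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from intervaltree import IntervalTree

from .sites import RunConfig, SiteError, TargetSite, window_positions

PROMOTED_MOTIFS = frozenset({"TAT", "TAC", "CAT", "GAC", "GAT"})
INHIBITED_MOTIFS = frozenset({"CAG", "AAG", "CAA", "AAA"})

#: factors whose union defines the CRE flag when no explicit CRE track is given
CRE_COMPONENT_FACTORS = ("DHS", "H3K4me3", "H3K27ac", "CTCF")


@dataclass
class EndoAnnotation:
    """Continuous and binary endogenous-factor values for one site."""

    site_id: str
    continuous: dict = field(default_factory=dict)
    binary: dict = field(default_factory=dict)
    per_base_methylation: dict = field(default_factory=dict)  # position -> beta
    metadata: dict = field(default_factory=dict)


@dataclass
class FactorEffect:
    factor: str
    coefficient: float
    p_value: float
    confounder: str = "n_target_bases_in_window"
    n: int = 0


# ---------------------------------------------------------------------------
# peak overlap


def _build_trees(intervals: Sequence[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def annotate_peaks(
    sites: Sequence[TargetSite],
    intervals_by_factor: Mapping[str, Sequence[tuple[str, int, int]]],
    cfg: RunConfig,
) -> dict[str, dict[str, Optional[int]]]:
    """Binary peak-overlap flags per site and factor.

    Flag is 1 iff the queried interval overlaps >= 1 bp of any peak.
    The queried interval is the 20-bp protospacer, widened by
    ``cfg.h3k27ac_flank`` on each side for H3K27ac.  Sites without a
    genomic anchor get ``None`` for every factor.
    """
    trees = {f: _build_trees(iv) for f, iv in intervals_by_factor.items()}
    out: dict[str, dict[str, Optional[int]]] = {}
    for site in sites:
        flags: dict[str, Optional[int]] = {}
        if site.chrom is None or site.start is None:
            flags = dict.fromkeys(intervals_by_factor, None)
        else:
            chrom, start, end = site.genomic_interval()
            for factor, chrom_trees in trees.items():
                if factor.upper() == "H3K27AC":
                    q0, q1 = start - cfg.h3k27ac_flank, end + cfg.h3k27ac_flank
                else:
                    q0, q1 = start, end
                tree = chrom_trees.get(chrom)
                flags[factor] = int(bool(tree is not None and tree.overlap(q0, q1)))
        out[site.site_id] = flags
    return out


# ---------------------------------------------------------------------------
# expression


def annotate_expression(
    sites: Sequence[TargetSite],
    gene_expression: Mapping[str, float],
    site_gene_map: Mapping[str, str],
    cfg: RunConfig,
) -> tuple[dict[str, float], dict[str, int]]:
    """Continuous (min-max of log2(TPM+1)) and binary (high/low)
    expression per site.

    The high/low threshold (default 1.5) applies on the log2(TPM+1)
    scale *before* min-max scaling; sites in unexpressed or unmapped
    genes (intergenic) are low with continuous value 0.
    """
    log_expr = {g: float(np.log2(v + 1.0)) for g, v in gene_expression.items()}
    vals = np.array(list(log_expr.values())) if log_expr else np.array([0.0])
    lo, hi = vals.min(), vals.max()
    span = hi - lo if hi > lo else 1.0
    continuous: dict[str, float] = {}
    binary: dict[str, int] = {}
    for site in sites:
        gene = site_gene_map.get(site.site_id)
        if gene is None or gene not in log_expr:
            continuous[site.site_id] = 0.0
            binary[site.site_id] = 0
        else:
            le = log_expr[gene]
            continuous[site.site_id] = (le - lo) / span
            binary[site.site_id] = int(le > cfg.expression_high_threshold)
    return continuous, binary


# ---------------------------------------------------------------------------
# methylation


def _abe_methylation_positions(site: TargetSite, window: tuple[int, int]) -> list[int]:
    """Window As inside an ACG or CGA trinucleotide (CpG-adjacent As)."""
    ctx = site.context40
    out = []
    for p in window_positions(window):
        i = 10 + p - 1  # context index of protospacer position p
        if ctx[i] != "A":
            continue
        if ctx[i : i + 3] == "ACG" or (i >= 2 and ctx[i - 2 : i + 1] == "CGA"):
            out.append(p)
    return out


def annotate_methylation(
    sites: Sequence[TargetSite],
    per_base_beta: pd.DataFrame,
    cfg: RunConfig,
) -> dict[str, EndoAnnotation]:
    """Site-level and per-base methylation annotation.

    Site-level methylation is the mean beta of covered bases inside the
    protospacer; the methylated flag requires mean beta strictly above
    ``cfg.methylation_high_threshold`` (0.75).  Per-base flags mark
    targeted Cs (CBE) or CpG-motif As (ABE, ACG/CGA) within the editing
    window that intersect a covered record.  Uncovered means
    unmethylated.
    """
    cov: dict[tuple[str, int], float] = {}
    for rec in per_base_beta.itertuples(index=False):
        for pos in range(int(rec.start), int(rec.end)):
            cov[(str(rec.chrom), pos)] = float(rec.value)

    out: dict[str, EndoAnnotation] = {}
    for site in sites:
        ann = EndoAnnotation(site_id=site.site_id)
        if site.chrom is None or site.start is None:
            ann.continuous["methylation"] = 0.0
            ann.binary["methylation"] = 0
            out[site.site_id] = ann
            continue
        chrom, start, end = site.genomic_interval()
        betas = []
        for p in range(1, 21):
            g = start + p - 1
            if (chrom, g) in cov:
                beta = cov[(chrom, g)]
                betas.append(beta)
                ann.per_base_methylation[p] = beta
        mean_beta = float(np.mean(betas)) if betas else 0.0
        ann.continuous["methylation"] = mean_beta
        ann.binary["methylation"] = int(mean_beta > cfg.methylation_high_threshold)
        if site.editor == "CBE":
            base_positions = site.target_positions(cfg.window)
        else:
            base_positions = _abe_methylation_positions(site, cfg.window)
        for p in base_positions:
            ann.binary[f"methylation_pos{p}"] = int(p in ann.per_base_methylation)
        out[site.site_id] = ann
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_factor(values: Sequence[float], kind: str = "signal") -> np.ndarray:
    """Min-max normalize factor values to [0, 1].

    Signal-like values (expression TPM, DNase RPF, histone/CTCF/Pol II
    fold change) are log2(x+1)-transformed first; methylation beta
    values are min-max scaled without the log.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SiteError("need >= 2 values for min-max normalization")
    if kind != "methylation":
        x = np.log2(x + 1.0)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise SiteError("degenerate min-max: constant input")
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# factor-vs-efficiency statistics


def factor_regression(
    efficiencies: Sequence[float],
    factor_values: Sequence[float],
    confounder_counts: Sequence[int],
    factor: str = "factor",
) -> FactorEffect:
    """Linear model efficiency ~ factor + count(target bases in window).

    Returns the factor coefficient and its two-sided p-value with the
    target-base count regressed out as a confounder.
    """
    y = np.asarray(efficiencies, dtype=float)
    if len(y) < 10:
        raise SiteError("need >= 10 sites for factor regression")
    X = np.column_stack(
        [np.asarray(factor_values, float), np.asarray(confounder_counts, float)]
    )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SiteError("collinear inputs in factor regression")
    fit = sm.OLS(y, design).fit()
    return FactorEffect(
        factor=factor,
        coefficient=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        n=len(y),
    )


def promoted_motif_ratio(
    motifs_by_group: Mapping[str, Sequence[str]]
) -> tuple[dict[str, float], float, float]:
    """Promoted-motif ratio per group with a 2x2 chi-squared test.

    Ratio = promoted / (promoted + inhibited) counting only motifs in
    the fixed promoted {TAT, TAC, CAT, GAC, GAT} and inhibited
    {CAG, AAG, CAA, AAA} lists; other motifs are excluded.  The test is
    chi-squared without continuity correction across the two groups.
    """
    if len(motifs_by_group) != 2:
        raise SiteError("promoted_motif_ratio expects exactly two groups")
    ratios: dict[str, float] = {}
    table = []
    for group, motifs in motifs_by_group.items():
        promoted = sum(1 for m in motifs if m.upper() in PROMOTED_MOTIFS)
        inhibited = sum(1 for m in motifs if m.upper() in INHIBITED_MOTIFS)
        if promoted + inhibited == 0:
            raise SiteError(f"group {group!r} has no promoted or inhibited motifs")
        ratios[group] = promoted / (promoted + inhibited)
        table.append([promoted, inhibited])
    chi2, p, _, _ = scipy.stats.chi2_contingency(np.array(table), correction=False)
    return ratios, float(chi2), float(p)


# ---------------------------------------------------------------------------
# assembled annotation


def build_annotations(
    sites: Sequence[TargetSite],
    cfg: RunConfig,
    peaks: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    gene_expression: Mapping[str, float] | None = None,
    site_gene_map: Mapping[str, str] | None = None,
    methylation: pd.DataFrame | None = None,
) -> dict[str, EndoAnnotation]:
    """Assemble the full per-site annotation from the raw tracks.

    The CRE flag is an explicit ``CRE`` peak track when provided,
    otherwise the union of the DHS, H3K4me3, H3K27ac and CTCF flags
    (recorded in the annotation as ``CRE_rule = "union"``).
    """
    anns = (
        annotate_methylation(sites, methylation, cfg)
        if methylation is not None
        else {s.site_id: EndoAnnotation(site_id=s.site_id) for s in sites}
    )
    if peaks:
        flags = annotate_peaks(sites, peaks, cfg)
        for site in sites:
            for factor, flag in flags[site.site_id].items():
                if flag is not None:
                    anns[site.site_id].binary[factor] = flag
                    anns[site.site_id].continuous[factor] = float(flag)
    if gene_expression is not None and site_gene_map is not None:
        cont, binr = annotate_expression(sites, gene_expression, site_gene_map, cfg)
        for site in sites:
            anns[site.site_id].continuous["expression"] = cont[site.site_id]
            anns[site.site_id].binary["expression"] = binr[site.site_id]
    for site in sites:
        b = anns[site.site_id].binary
        if "CRE" not in b:
            components = [b.get(f) for f in CRE_COMPONENT_FACTORS if b.get(f) is not None]
            if components:
                b["CRE"] = int(any(components))
                anns[site.site_id].continuous["CRE"] = float(b["CRE"])
                anns[site.site_id].metadata["CRE_rule"] = "union(DHS,H3K4me3,H3K27ac,CTCF)"
    return anns
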
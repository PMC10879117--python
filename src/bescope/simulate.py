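"""Synthetic base-editing datasets with known ground truth.

The generator emulates the phenomena the analysis modules quantify:
motif- and position-dependent per-base editing marginals, endogenous-
factor effects on those marginals (on the logit scale), adjacent-
position co-editing described by an odds ratio, flat-rate bystander
(unintended) transitions, 1-bp indels with an insertion peak at
protospacer position 18 and deletions inside the editing window, and
multinomial replicate noise at fixed read depth.

Everything is a pure function of (parameters, seed).  Default parameter
values are chosen to mimic endogenous-editing data: moderate window
marginals spanning a wide range across sites, near-zero editing outside
the window, positive co-editing (c = 4), and factor effect signs that
match the direction each factor pushes editing (e.g. methylation
suppresses C-to-T editing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .endo import build_annotations
from .proportion import joint_from_margins_or
from .sites import (
    DEFAULT_WINDOW,
    PRODUCT_BASE,
    TARGET_BASE,
    AlleleRow,
    AlleleTable,
    RunConfig,
    TargetSite,
)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_GAP = 4

#: default logit coefficients of each endogenous factor, per editor
DEFAULT_FACTOR_EFFECTS = {
    "CBE": {
        "expression": 0.6, "PolII": 0.4, "CTCF": 0.4, "DHS": 0.5,
        "H3K4me3": 0.4, "H3K27ac": 0.5, "H3K36me3": 0.3,
        "methylation": -0.8,
    },
    "ABE": {
        "expression": 0.2, "H3K27ac": -0.4, "methylation": 0.3,
    },
}

#: peak placement probability per factor (fraction of sites with a peak)
DEFAULT_PEAK_RATES = {
    "PolII": 0.12, "CTCF": 0.10, "DHS": 0.20, "H3K4me1": 0.08,
    "H3K4me3": 0.15, "H3K27ac": 0.20, "H3K36me3": 0.35,
}


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters."""

    editor: str = "ABE"
    base_logit: float = -0.8
    #: extra logit outside the editing window (editing collapses there)
    out_of_window_logit: float = -4.5
    near_window_logit: float = -2.5
    #: logit offset per 3-mer context (center = target base)
    motif_effects: dict = field(default_factory=dict)
    motif_scale: float = 0.8
    factor_effects: dict = field(default_factory=dict)
    #: adjacent-position co-editing odds ratio
    c: float = 4.0
    bystander_rate: float = 0.002
    insertion18_rate: float = 0.008
    window_deletion_rate: float = 0.003
    peak_rates: dict = field(default_factory=dict)
    methylated_fraction: float = 0.3
    expressed_fraction: float = 0.75
    overdispersion: float = 0.0
    seed: int = 0

    @classmethod
    def default(cls, editor: str, seed: int = 0, **overrides) -> "SyntheticTruth":
        truth = cls(editor=editor, seed=seed, **overrides)
        if not truth.factor_effects:
            truth.factor_effects = dict(DEFAULT_FACTOR_EFFECTS[editor])
        if not truth.peak_rates:
            truth.peak_rates = dict(DEFAULT_PEAK_RATES)
        if not truth.motif_effects:
            rng = np.random.default_rng(seed + 17)
            target = TARGET_BASE[editor]
            truth.motif_effects = {
                up + target + down: float(rng.normal(0.0, truth.motif_scale))
                for up in BASES
                for down in BASES
            }
        return truth

    # ------------------------------------------------------------------
    def marginals(
        self, site: TargetSite, factor_values: Mapping[str, float]
    ) -> np.ndarray:
        """True P(edit) at each protospacer position 1-20 (NaN at
        non-target positions)."""
        window = DEFAULT_WINDOW[self.editor]
        factor_term = sum(
            beta * float(factor_values.get(f, 0.0))
            for f, beta in self.factor_effects.items()
        )
        out = np.full(20, np.nan)
        for p in range(1, 21):
            if site.base_at(p) != TARGET_BASE[self.editor]:
                continue
            i = 10 + p - 1
            motif = site.context40[i - 1 : i + 2]
            logit = self.base_logit + self.motif_effects.get(motif, 0.0) + factor_term
            if window[0] <= p <= window[1]:
                pass
            elif window[0] - 1 <= p <= window[1] + 1:
                logit += self.near_window_logit
            else:
                logit += self.out_of_window_logit
            out[p - 1] = 1.0 / (1.0 + np.exp(-logit))
        return out


# ---------------------------------------------------------------------------
# sites


def generate_sites(
    n: int, editor: str, seed: int, dataset: str = "synthetic"
) -> list[TargetSite]:
    """Random 40-nt contexts with an NGG PAM and at least one target
    base inside the editor's window; deterministic per seed, spaced
    1 kb apart on a synthetic chromosome."""
    rng = np.random.default_rng(seed)
    window = DEFAULT_WINDOW[editor]
    target = TARGET_BASE[editor]
    sites = []
    for i in range(n):
        while True:
            seq = rng.integers(0, 4, size=40)
            seq[31] = _CODE["G"]
            seq[32] = _CODE["G"]
            ctx = "".join(BASES[b] for b in seq)
            proto = ctx[10:30]
            if any(proto[p - 1] == target for p in range(window[0], window[1] + 1)):
                break
        sites.append(
            TargetSite(
                site_id=f"site{i:05d}",
                editor=editor,
                context40=ctx,
                chrom="chrSYN",
                start=1000 * (i + 1),
                strand="+",
                dataset=dataset,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# endogenous factors


@dataclass
class SyntheticTracks:
    peaks: dict                      # factor -> list[(chrom, start, end)]
    gene_expression: dict            # gene -> TPM
    site_gene_map: dict              # site_id -> gene
    methylation: pd.DataFrame        # chrom/start/end/value per base

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for factor, intervals in self.peaks.items():
            bio.write_bed(intervals, outdir / f"{factor}.bed")
        pd.DataFrame(
            {"gene": list(self.gene_expression), "tpm": list(self.gene_expression.values())}
        ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"site_id": list(self.site_gene_map), "gene": list(self.site_gene_map.values())}
        ).to_csv(outdir / "site_genes.tsv", sep="\t", index=False)
        bio.write_bedgraph(self.methylation, outdir / "methylation.bedgraph")


def generate_annotations(
    sites: Sequence[TargetSite],
    truth: SyntheticTruth,
    seed: int,
    cfg: Optional[RunConfig] = None,
) -> tuple[dict, SyntheticTracks, dict]:
    """Emit raw factor tracks plus the per-site annotations and the
    ground-truth factor values that feed the editing marginals.

    The annotations are derived from the emitted tracks through the
    annotation module itself, so annotating the written files
    reproduces them exactly.
    """
    cfg = cfg or RunConfig(editor=truth.editor, seed=seed)
    rng = np.random.default_rng(seed)
    peaks: dict[str, list] = {}
    for factor, rate in truth.peak_rates.items():
        intervals = []
        for site in sites:
            if rng.random() < rate:
                chrom, start, end = site.genomic_interval()
                intervals.append((chrom, start - 10, end + 10))
        peaks[factor] = intervals

    gene_expression: dict[str, float] = {}
    site_gene_map: dict[str, str] = {}
    for site in sites:
        gene = f"gene_{site.site_id}"
        site_gene_map[site.site_id] = gene
        if rng.random() < truth.expressed_fraction:
            gene_expression[gene] = float(rng.lognormal(mean=1.5, sigma=1.2))
        else:
            gene_expression[gene] = 0.0

    meth_rows = []
    for site in sites:
        chrom, start, end = site.genomic_interval()
        u = rng.random()
        if u < truth.methylated_fraction:
            betas = rng.beta(8, 1.2, size=20)
        elif u < truth.methylated_fraction + 0.3:
            betas = rng.beta(1, 10, size=20)
        else:
            continue  # uncovered site
        for off, beta in enumerate(betas):
            meth_rows.append((chrom, start + off, start + off + 1, round(float(beta), 4)))
    methylation = pd.DataFrame(meth_rows, columns=["chrom", "start", "end", "value"])

    tracks = SyntheticTracks(
        peaks=peaks,
        gene_expression=gene_expression,
        site_gene_map=site_gene_map,
        methylation=methylation,
    )
    annotations = build_annotations(
        sites, cfg,
        peaks=peaks,
        gene_expression=gene_expression,
        site_gene_map=site_gene_map,
        methylation=methylation,
    )
    factor_values = {
        sid: {
            **{f: float(v) for f, v in ann.binary.items() if not f.startswith("methylation_pos")},
            "expression": ann.continuous.get("expression", 0.0),
            "methylation": ann.continuous.get("methylation", 0.0),
        }
        for sid, ann in annotations.items()
    }
    return annotations, tracks, factor_values


# ---------------------------------------------------------------------------
# allele-table sampling


def _sample_patterns(
    m: np.ndarray, positions: Sequence[int], c: float, n_reads: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample (n_reads, len(positions)) edit indicators from the chain."""
    k = len(positions)
    x = np.zeros((n_reads, k), dtype=bool)
    if k == 0:
        return x
    probs = np.clip(np.array([m[p - 1] for p in positions]), 1e-6, 1 - 1e-6)
    x[:, 0] = rng.random(n_reads) < probs[0]
    for i in range(1, k):
        j = joint_from_margins_or(probs[i - 1], probs[i], c)
        g1 = j.p11 / (j.p11 + j.p10)
        g0 = j.p01 / (j.p01 + j.p00)
        x[:, i] = rng.random(n_reads) < np.where(x[:, i - 1], g1, g0)
    return x


def sample_allele_tables(
    site: TargetSite,
    truth: SyntheticTruth,
    factor_values: Mapping[str, float],
    n_reads: int,
    replicates: int,
    seed: int,
) -> list[AlleleTable]:
    """Draw replicate allele tables for one site.

    Reads follow the chain outcome distribution over the site's target
    bases; bystander transitions, window 1-bp deletions and position-18
    1-bp insertions are superimposed independently.  The reference is
    the 40-nt context, so protospacer position 1 sits at index 10.
    """
    rng = np.random.default_rng(seed)
    m = truth.marginals(site, factor_values)
    positions = site.target_positions()
    product_code = _CODE[PRODUCT_BASE[site.editor]]
    ref_codes = np.array([_CODE[b] for b in site.context40], dtype=np.int8)
    window = DEFAULT_WINDOW[site.editor]

    tables = []
    for rep in range(replicates):
        depth = n_reads
        if truth.overdispersion > 0:
            depth = max(1, int(rng.normal(n_reads, truth.overdispersion * n_reads)))
        x = _sample_patterns(m, positions, truth.c, depth, rng)
        reads = np.tile(ref_codes, (depth, 1))
        for j, p in enumerate(positions):
            reads[x[:, j], 10 + p - 1] = product_code
        # flat-rate bystander (unintended) substitutions in the protospacer
        if truth.bystander_rate > 0:
            by = rng.random((depth, 20)) < truth.bystander_rate
            for j, p in enumerate(positions):
                by[x[:, j], p - 1] = False
            rows_, cols_ = np.nonzero(by)
            if rows_.size:
                shift = rng.integers(1, 4, size=rows_.size).astype(np.int8)
                idx = 10 + cols_
                reads[rows_, idx] = (reads[rows_, idx] + shift) % 4
        # 1-bp deletions inside the editing window
        if truth.window_deletion_rate > 0:
            for p in range(window[0], window[1] + 1):
                dmask = rng.random(depth) < truth.window_deletion_rate
                reads[dmask, 10 + p - 1] = _GAP
        # 1-bp insertion between protospacer positions 17 and 18
        ins_base = np.full(depth, -1, dtype=np.int8)
        if truth.insertion18_rate > 0:
            imask = rng.random(depth) < truth.insertion18_rate
            ins_base[imask] = rng.integers(0, 4, size=int(imask.sum())).astype(np.int8)

        # aggregate identical reads: exact base-6 packing of the 41
        # symbols (40 alignment codes + insertion state) into two uint64
        # keys, then a lexsort -- equivalent to a row-wise unique
        stacked = np.column_stack([reads, ins_base + 1]).astype(np.uint64)
        pow_a = 6 ** np.arange(21, dtype=np.uint64)
        pow_b = 6 ** np.arange(stacked.shape[1] - 21, dtype=np.uint64)
        key_a = (stacked[:, :21] * pow_a).sum(axis=1)
        key_b = (stacked[:, 21:] * pow_b).sum(axis=1)
        order = np.lexsort((key_b, key_a))
        ka, kb = key_a[order], key_b[order]
        boundary = np.flatnonzero(
            np.r_[True, (ka[1:] != ka[:-1]) | (kb[1:] != kb[:-1])]
        )
        counts = np.diff(np.r_[boundary, len(ka)])
        rows = []
        for ridx, cnt in zip(order[boundary], counts):
            codes, ib = reads[ridx], int(ins_base[ridx])
            aligned = "".join("-" if cd == _GAP else BASES[cd] for cd in codes)
            insertions = ((10 + 17, BASES[ib]),) if ib >= 0 else ()
            rows.append(
                AlleleRow(
                    aligned=aligned,
                    n_reads=int(cnt),
                    n_inserted=1 if ib >= 0 else 0,
                    n_deleted=aligned.count("-"),
                    insertions=insertions,
                )
            )
        tables.append(
            AlleleTable(
                site_id=site.site_id,
                replicate_id=f"r{rep + 1}",
                reference=site.context40,
                rows=rows,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# full datasets


@dataclass
class SimulatedDataset:
    sites: list
    truth: SyntheticTruth
    annotations: dict
    tracks: SyntheticTracks
    factor_values: dict
    tables: dict                      # site_id -> list[AlleleTable]
    true_marginals: dict              # site_id -> np.ndarray(20)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_sites(self.sites, outdir / "sites.tsv")
        self.tracks.write(outdir / "tracks")
        alleles_dir = outdir / "alleles"
        alleles_dir.mkdir(exist_ok=True)
        for sid, tables in self.tables.items():
            for t in tables:
                bio.write_allele_table(t, alleles_dir / f"{sid}__{t.replicate_id}.tsv")
        import json

        truth_info = {
            "editor": self.truth.editor,
            "c": self.truth.c,
            "base_logit": self.truth.base_logit,
            "factor_effects": self.truth.factor_effects,
            "motif_effects": self.truth.motif_effects,
            "seed": self.truth.seed,
            "true_marginals": {k: list(map(float, np.nan_to_num(v)))
                               for k, v in self.true_marginals.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth_info))


def simulate_dataset(
    n_sites: int,
    editor: str,
    depth: int,
    replicates: int,
    seed: int,
    truth: Optional[SyntheticTruth] = None,
) -> SimulatedDataset:
    """Generate sites, tracks, annotations and allele tables end to end."""
    truth = truth or SyntheticTruth.default(editor, seed=seed)
    sites = generate_sites(n_sites, editor, seed)
    annotations, tracks, factor_values = generate_annotations(sites, truth, seed + 1)
    tables = {}
    true_marginals = {}
    ss = np.random.SeedSequence(entropy=seed + 2)
    child_seeds = ss.generate_state(n_sites)
    for site, cs in zip(sites, child_seeds):
        fv = factor_values[site.site_id]
        true_marginals[site.site_id] = truth.marginals(site, fv)
        tables[site.site_id] = sample_allele_tables(
            site, truth, fv, depth, replicates, int(cs % (2**31))
        )
    return SimulatedDataset(
        sites=sites,
        truth=truth,
        annotations=annotations,
        tracks=tracks,
        factor_values=factor_values,
        tables=tables,
        true_marginals=true_marginals,
    )
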
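"""Per-site and cross-site editing statistics from allele tables.

Implements the read-count-weighted efficiency formulas, the 12-transition
purity proportions, 1-bp indel profiling with the interquartile site
filter, editing:indel ratios, replicate-concordance filters, editing
outcome distributions, and the endogenous-vs-integrated bias groupings.

Efficiency definitions (all denominators are total aligned reads):

* overall efficiency      -- reads carrying the intended transition
                             (A->G for ABE, C->T for CBE) at any target
                             base inside the editing window;
* per-position efficiency -- reads carrying the intended transition at
                             that protospacer position (defined only
                             where the reference base is the target base);
* modified efficiency     -- reads carrying any substitution or indel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .sites import (
    DEAMINASE_REGION,
    NCAS9_REGION,
    PRODUCT_BASE,
    TRANSITIONS,
    AlleleTable,
    RunConfig,
    SiteError,
    TargetSite,
    window_positions,
)

logger = logging.getLogger(__name__)

SCOPES = ("overall", "in_window", "outside_window")


# ---------------------------------------------------------------------------
# per-read decomposition


@dataclass(frozen=True)
class ReadEvents:
    """Edits carried by one allele, in protospacer coordinates."""

    substitutions: tuple[tuple[int, str, str], ...]  # (pos 1-20, ref, alt)
    intended: frozenset[int]          # positions with the intended transition
    indels: tuple[tuple[int, int], ...]  # (pos 1-20, signed length)
    any_mutation: bool                # any substitution or indel, whole reference


def decompose_read(
    aligned: str,
    reference: str,
    insertions: Sequence[tuple[int, str]],
    offset: int,
    site: TargetSite,
) -> ReadEvents:
    """Classify one aligned allele against the reference.

    ``offset`` is the 0-based reference index of protospacer position 1.
    Deletions are attributed to the first deleted base inside the
    protospacer; insertions to the protospacer position of the reference
    base immediately 3' of the insertion point.  Events entirely outside
    positions 1-20 are not attributed to any protospacer position but do
    count toward ``any_mutation``.
    """
    target, product = site.target_base, PRODUCT_BASE[site.editor]
    subs, intended = [], []
    any_mut = bool(insertions)
    for i, (a, r) in enumerate(zip(aligned, reference)):
        if a == r or a == "-":
            continue
        any_mut = True
        pos = i - offset + 1
        if 1 <= pos <= 20:
            subs.append((pos, r, a))
            if r == target and a == product:
                intended.append(pos)
    indels = []
    # deletion runs
    i = 0
    n = len(aligned)
    while i < n:
        if aligned[i] == "-":
            j = i
            while j < n and aligned[j] == "-":
                j += 1
            any_mut = True
            run_positions = [k - offset + 1 for k in range(i, j) if 1 <= k - offset + 1 <= 20]
            if run_positions:
                indels.append((min(run_positions), -(j - i)))
            i = j
        else:
            i += 1
    for ref_idx, seq in insertions:
        pos = ref_idx - offset + 1
        if 1 <= pos <= 20:
            indels.append((pos, len(seq)))
    return ReadEvents(
        substitutions=tuple(subs),
        intended=frozenset(intended),
        indels=tuple(indels),
        any_mutation=any_mut,
    )


# ---------------------------------------------------------------------------
# site summary


@dataclass
class SiteEditingSummary:
    """All per-site efficiency / purity / indel statistics."""

    site_id: str
    editor: str
    overall_efficiency: float = 0.0
    per_position_efficiency: list = field(default_factory=lambda: [None] * 20)
    modified_efficiency: float = 0.0
    transition_proportions: dict = field(default_factory=dict)
    indel_by_position_length: dict = field(default_factory=dict)
    deaminase_indel_freq: float = 0.0
    ncas9_indel_freq: float = 0.0
    total_reads: int = 0
    n_replicates: int = 1


def _in_region(pos: int, region: tuple[int, int]) -> bool:
    return region[0] <= pos <= region[1]


def summarize_site(
    table: AlleleTable, site: TargetSite, cfg: RunConfig
) -> SiteEditingSummary:
    """Compute every per-site statistic for one replicate."""
    offset = table.protospacer_offset(site)
    window = cfg.window
    total = table.total_reads
    wpos = set(window_positions(window))

    n_overall = 0
    n_modified = 0
    per_pos = np.zeros(20)
    trans_counts = {scope: dict.fromkeys(TRANSITIONS, 0.0) for scope in SCOPES}
    indel_counts: dict[tuple[int, int], float] = {}
    n_deaminase = 0
    n_ncas9 = 0

    for row in table.rows:
        ev = decompose_read(row.aligned, table.reference, row.insertions, offset, site)
        w = row.n_reads
        if ev.intended & wpos:
            n_overall += w
        if ev.any_mutation:
            n_modified += w
        for p in ev.intended:
            per_pos[p - 1] += w
        # purity: a read counts once per transition type per scope
        seen: dict[str, set] = {s: set() for s in SCOPES}
        for pos, r, a in ev.substitutions:
            t = f"{r}>{a}"
            seen["overall"].add(t)
            seen["in_window" if pos in wpos else "outside_window"].add(t)
        for scope, ts in seen.items():
            for t in ts:
                trans_counts[scope][t] += w
        seen_indels = set(ev.indels)
        for pos, length in seen_indels:
            indel_counts[(pos, length)] = indel_counts.get((pos, length), 0.0) + w
        if any(_in_region(p, DEAMINASE_REGION) for p, _ in seen_indels):
            n_deaminase += w
        if any(_in_region(p, NCAS9_REGION) for p, _ in seen_indels):
            n_ncas9 += w

    # normalize the 12 transitions to sum to 1 within each scope
    trans_prop: dict[str, dict[str, float]] = {}
    for scope in SCOPES:
        s = sum(trans_counts[scope].values())
        if s > 0:
            trans_prop[scope] = {
                t: c / s for t, c in trans_counts[scope].items() if c > 0
            }
        else:
            trans_prop[scope] = {}

    per_position = [
        per_pos[p - 1] / total if site.base_at(p) == site.target_base else None
        for p in range(1, 21)
    ]
    return SiteEditingSummary(
        site_id=site.site_id,
        editor=site.editor,
        overall_efficiency=n_overall / total,
        per_position_efficiency=per_position,
        modified_efficiency=n_modified / total,
        transition_proportions=trans_prop,
        indel_by_position_length={k: v / total for k, v in indel_counts.items()},
        deaminase_indel_freq=n_deaminase / total,
        ncas9_indel_freq=n_ncas9 / total,
        total_reads=total,
    )


def average_replicates(
    summaries: Sequence[SiteEditingSummary], cfg: RunConfig
) -> Optional[SiteEditingSummary]:
    """Average biological replicates of one site, field-wise.

    Replicates under ``cfg.min_coverage`` total reads are excluded first;
    if none survive the site is dropped (returns ``None``, logged).
    """
    if not summaries:
        raise SiteError("no replicates supplied")
    site_id = summaries[0].site_id
    kept = [s for s in summaries if s.total_reads >= cfg.min_coverage]
    if not kept:
        logger.warning(
            "site %s dropped: all %d replicate(s) below coverage %d",
            site_id, len(summaries), cfg.min_coverage,
        )
        return None

    k = len(kept)
    per_pos = []
    for i in range(20):
        vals = [s.per_position_efficiency[i] for s in kept]
        per_pos.append(None if vals[0] is None else float(np.mean([v for v in vals])))

    trans: dict[str, dict[str, float]] = {}
    for scope in SCOPES:
        reps = [s.transition_proportions.get(scope, {}) for s in kept]
        reps = [r for r in reps if r]
        if not reps:
            trans[scope] = {}
            continue
        keys = sorted(set().union(*reps))
        trans[scope] = {t: float(np.mean([r.get(t, 0.0) for r in reps])) for t in keys}

    indel_keys = sorted(set().union(*[set(s.indel_by_position_length) for s in kept]))
    indels = {
        key: float(np.mean([s.indel_by_position_length.get(key, 0.0) for s in kept]))
        for key in indel_keys
    }
    return SiteEditingSummary(
        site_id=site_id,
        editor=kept[0].editor,
        overall_efficiency=float(np.mean([s.overall_efficiency for s in kept])),
        per_position_efficiency=per_pos,
        modified_efficiency=float(np.mean([s.modified_efficiency for s in kept])),
        transition_proportions=trans,
        indel_by_position_length=indels,
        deaminase_indel_freq=float(np.mean([s.deaminase_indel_freq for s in kept])),
        ncas9_indel_freq=float(np.mean([s.ncas9_indel_freq for s in kept])),
        total_reads=sum(s.total_reads for s in kept),
        n_replicates=k,
    )


# ---------------------------------------------------------------------------
# 1-bp indel profiling across sites


def indel_position_profile(
    summaries: Sequence[SiteEditingSummary],
    lengths: Sequence[int] = (1, -1),
    normalize_by_length: bool = True,
) -> dict[int, np.ndarray]:
    """Per-position mean indel frequency over sites, per signed length.

    For each length, sites are ranked by their total frequency of events
    of that length and only sites with frequency within the 25th-75th
    percentile band (linear-interpolation quantiles, boundaries
    inclusive) are retained.  Frequencies are divided by |length| when
    ``normalize_by_length``.
    """
    if len(summaries) < 4:
        raise SiteError("insufficient sites for percentile filter (need >= 4)")
    out: dict[int, np.ndarray] = {}
    for length in lengths:
        site_freq = np.array(
            [
                sum(v for (p, l), v in s.indel_by_position_length.items() if l == length)
                for s in summaries
            ]
        )
        q25, q75 = np.percentile(site_freq, [25, 75])
        keep = (site_freq >= q25) & (site_freq <= q75)
        profile = np.zeros(20)
        denom = max(int(keep.sum()), 1)
        for s, k in zip(summaries, keep):
            if not k:
                continue
            for (p, l), v in s.indel_by_position_length.items():
                if l == length:
                    profile[p - 1] += (v / abs(length)) if normalize_by_length else v
        out[length] = profile / denom
    return out


def be_indel_ratio(
    summaries: Sequence[SiteEditingSummary], region: str
) -> tuple[float, dict[str, float]]:
    """Geometric-mean ratio of editing efficiency to indel frequency.

    ``region`` is ``"deaminase"`` (positions 1-11) or ``"ncas9"``
    (positions 14-20).  Sites without indel reads in the region are
    excluded (division by zero), as are sites with zero efficiency
    (the log is undefined); exclusions are logged.
    """
    attr = {"deaminase": "deaminase_indel_freq", "ncas9": "ncas9_indel_freq"}[region]
    ratios: dict[str, float] = {}
    for s in summaries:
        f = getattr(s, attr)
        if f <= 0 or s.overall_efficiency <= 0:
            logger.info("site %s excluded from %s ratio (zero numerator/denominator)",
                        s.site_id, region)
            continue
        ratios[s.site_id] = s.overall_efficiency / f
    if not ratios:
        raise SiteError(f"no site with nonzero {region} indels and nonzero efficiency")
    gm = math.exp(float(np.mean([math.log(r) for r in ratios.values()])))
    return gm, ratios


# ---------------------------------------------------------------------------
# replicate filtering for outcome analysis


def _allele_key(row) -> tuple:
    return (row.aligned, row.insertions)


def _modified_fraction(table: AlleleTable) -> float:
    mod = sum(
        r.n_reads
        for r in table.rows
        if r.aligned != table.reference or r.insertions
    )
    return mod / table.total_reads


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P||Q) in nats for strictly positive distributions."""
    return float(np.sum(p * np.log(p / q)))


def filter_outcome_replicates(
    tables: Sequence[AlleleTable], cfg: RunConfig
) -> list[AlleleTable]:
    """Replicate-concordance filter for editing-outcome analysis.

    Removes replicates whose edited-read fraction Ne/Nt falls below
    ``cfg.edited_fraction_threshold`` (0.9), then replicates whose mean
    pairwise KL divergence between pseudocount-smoothed allele
    distributions exceeds the Tukey fence Q3 + 1.5 IQR.
    """
    kept = [t for t in tables if _modified_fraction(t) >= cfg.edited_fraction_threshold]
    if len(kept) < len(tables):
        logger.info("removed %d replicate(s) below edited-fraction threshold",
                    len(tables) - len(kept))
    if len(kept) <= 2:
        return kept
    alleles = sorted(set().union(*[{_allele_key(r) for r in t.rows} for t in kept]))
    dists = []
    for t in kept:
        counts = dict.fromkeys(alleles, 0.0)
        for r in t.rows:
            counts[_allele_key(r)] += r.n_reads
        v = np.array([counts[a] for a in alleles]) + cfg.kl_pseudocount
        dists.append(v / v.sum())
    mean_kl = np.array(
        [
            np.mean([kl_divergence(dists[i], dists[j]) for j in range(len(kept)) if j != i])
            for i in range(len(kept))
        ]
    )
    q1, q3 = np.percentile(mean_kl, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    out = [t for t, kl in zip(kept, mean_kl) if kl <= fence]
    if len(out) < len(kept):
        logger.info("removed %d replicate(s) as KL outliers", len(kept) - len(out))
    return out


# ---------------------------------------------------------------------------
# outcome distributions


@dataclass(frozen=True)
class OutcomeAllele:
    """One editing product: which target bases carry the intended
    transition (pattern over positions 1-20, '1' = edited) plus any
    non-intended substitutions kept as a side annotation."""

    pattern: str
    proportion: float
    side: str = ""

    @property
    def edited_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, c in enumerate(self.pattern) if c == "1")

    @property
    def n_edited(self) -> int:
        return self.pattern.count("1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.pattern, self.side)


@dataclass
class OutcomeDistribution:
    """Normalized editing-outcome proportions for one site."""

    site_id: str
    alleles: list[OutcomeAllele] = field(default_factory=list)
    provenance: str = "observed"

    @property
    def empty(self) -> bool:
        return not self.alleles

    def total(self) -> float:
        return sum(a.proportion for a in self.alleles)

    def allele_keys(self) -> set:
        return {a.key for a in self.alleles}

    def by_pattern(self) -> dict[str, float]:
        """Proportions aggregated over side annotations."""
        out: dict[str, float] = {}
        for a in self.alleles:
            out[a.pattern] = out.get(a.pattern, 0.0) + a.proportion
        return out


def pattern_string(positions: Iterable[int]) -> str:
    chars = ["."] * 20
    for p in positions:
        chars[p - 1] = "1"
    return "".join(chars)


def collapse_outcomes(
    tables: Sequence[AlleleTable], site: TargetSite, cfg: RunConfig
) -> OutcomeDistribution:
    """Pool replicates into one editing-outcome distribution.

    Read counts are pooled across replicates; reads with indels and the
    wild-type allele are removed; proportions are normalized, alleles at
    or below ``cfg.allele_proportion_threshold`` are dropped, and the
    remainder renormalized to 1.
    """
    counts: dict[tuple[str, str], float] = {}
    for table in tables:
        offset = table.protospacer_offset(site)
        for row in table.rows:
            ev = decompose_read(row.aligned, table.reference, row.insertions, offset, site)
            if ev.indels or "-" in row.aligned or row.insertions:
                continue  # outcome analysis is over editing alleles
            if not ev.any_mutation:
                continue  # wild type removed
            pattern = pattern_string(ev.intended)
            side = ";".join(
                f"{p}{r}>{a}" for p, r, a in ev.substitutions
                if not (p in ev.intended)
            )
            key = (pattern, side)
            counts[key] = counts.get(key, 0.0) + row.n_reads
    total = sum(counts.values())
    if total == 0:
        return OutcomeDistribution(site_id=site.site_id, alleles=[])
    props = {k: v / total for k, v in counts.items()}
    kept = {k: v for k, v in props.items() if v > cfg.allele_proportion_threshold}
    if not kept:
        return OutcomeDistribution(site_id=site.site_id, alleles=[])
    z = sum(kept.values())
    alleles = [
        OutcomeAllele(pattern=k[0], side=k[1], proportion=v / z)
        for k, v in sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return OutcomeDistribution(site_id=site.site_id, alleles=alleles)


def observed_pattern_distribution(
    tables: Sequence[AlleleTable], site: TargetSite
) -> tuple[dict[str, float], int]:
    """Raw edit-pattern proportions pooled over replicates.

    Unlike :func:`collapse_outcomes` this keeps the wild-type pattern
    and applies no proportion threshold, aggregating purely by which
    target bases carry the intended transition -- the estimator input
    for adjacent odds ratios and the mutual-information audit.  Reads
    with indels are excluded.  Returns (pattern -> proportion, number
    of reads used).
    """
    counts: dict[str, float] = {}
    used = 0
    for table in tables:
        offset = table.protospacer_offset(site)
        for row in table.rows:
            if "-" in row.aligned or row.insertions:
                continue
            ev = decompose_read(row.aligned, table.reference, row.insertions, offset, site)
            pattern = pattern_string(ev.intended)
            counts[pattern] = counts.get(pattern, 0.0) + row.n_reads
            used += row.n_reads
    if used == 0:
        return {}, 0
    return {k: v / used for k, v in counts.items()}, used


def classify_outcome_consistency(
    endo: OutcomeDistribution, inte: OutcomeDistribution
) -> str:
    """Four-group consistency label from the two allele sets."""
    if endo.empty or inte.empty:
        raise SiteError("cannot classify consistency with an empty distribution")
    e, i = endo.allele_keys(), inte.allele_keys()
    if e == i:
        return "Consistent"
    if e > i:
        return "Endo-bias"
    if i > e:
        return "Inte-bias"
    return "Discordant"


# ---------------------------------------------------------------------------
# efficiency bias grouping


@dataclass
class BiasGroups:
    site_ids: list[str]
    labels: list[str]
    slope: float
    intercept: float
    residual_mu: float
    residual_sigma: float
    residuals: np.ndarray


def classify_efficiency_bias(
    site_ids: Sequence[str],
    endo_efficiency: Sequence[float],
    inte_efficiency: Sequence[float],
) -> BiasGroups:
    """mu +/- sigma grouping of paired endogenous/integrated efficiencies.

    Ordinary least squares of endogenous on integrated efficiency;
    residual d_i = observed - fitted; sites with d_i > mu + sigma are
    Endo-bias, d_i < mu - sigma are Inte-bias, the rest Consistent.
    sigma is the population standard deviation of the residuals; a zero
    sigma band degenerates to all-Consistent.
    """
    x = np.asarray(inte_efficiency, dtype=float)
    y = np.asarray(endo_efficiency, dtype=float)
    if len(x) < 3:
        raise SiteError("need >= 3 paired sites")
    if np.ptp(x) == 0:
        raise SiteError("degenerate regression: zero variance in integrated efficiency")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    mu = float(np.mean(resid))
    sigma = float(np.std(resid))  # population sd
    if sigma <= 1e-12 * max(1.0, float(np.abs(y).max())):
        sigma = 0.0  # numerically exact fit: zero-width band cannot exclude
    labels = []
    for d in resid:
        if sigma > 0 and d > mu + sigma:
            labels.append("Endo-bias")
        elif sigma > 0 and d < mu - sigma:
            labels.append("Inte-bias")
        else:
            labels.append("Consistent")
    return BiasGroups(
        site_ids=list(site_ids),
        labels=labels,
        slope=float(slope),
        intercept=float(intercept),
        residual_mu=mu,
        residual_sigma=sigma,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# outcome-pattern statistics


def cooccurrence_matrix(
    outcomes: OutcomeDistribution, positions: Optional[Sequence[int]] = None
) -> tuple[list[int], np.ndarray]:
    """Pairwise co-edit proportions over target-base positions.

    Entry (i, j) is the summed proportion of alleles edited at both
    positions; the diagonal holds the marginal edit proportions.
    """
    if positions is None:
        positions = sorted(set().union(*[set(a.edited_positions) for a in outcomes.alleles]))\
            if outcomes.alleles else []
    positions = list(positions)
    m = np.zeros((len(positions), len(positions)))
    for a in outcomes.alleles:
        edited = set(a.edited_positions)
        for i, p in enumerate(positions):
            if p not in edited:
                continue
            for j, q in enumerate(positions):
                if q in edited:
                    m[i, j] += a.proportion
    return positions, m


def edited_base_count_distribution(outcomes: OutcomeDistribution) -> dict[int, float]:
    """Proportion-weighted histogram of edited target bases per allele."""
    hist: dict[int, float] = {}
    for a in outcomes.alleles:
        hist[a.n_edited] = hist.get(a.n_edited, 0.0) + a.proportion
    return hist
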
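"""Two-caller deletion consensus, cross-sample merging and deletion burden.

Per-sample deletion calls from two independent callers (read-depth and
split-read based in the original workflow) are intersected: a call is kept
when the other caller supports it with reciprocal overlap >= 0.20 in the
same sample, unless both members of the pair failed caller QC.  Retained
per-sample events drop out if they reciprocally overlap a known benign
deletion region; survivors are merged across samples by single-linkage
clustering at reciprocal overlap >= 0.50, filtered to cohort frequency
strictly below 1/1000 and to events intersecting at least one exon of a
protein-coding gene, and tested per gene with the same one-tailed Fisher /
Bonferroni machinery as the SNV burden scan.

All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .burden import CarrierTable, fisher_one_tailed

__all__ = [
    "DeletionCall",
    "ConsensusDeletion",
    "reciprocal_overlap",
    "intersect_callers",
    "exclude_benign",
    "merge_across_samples",
    "filter_frequency_and_exons",
    "deletion_burden",
]


@dataclass(frozen=True)
class DeletionCall:
    sample: str
    caller: str
    chrom: str
    start: int
    end: int
    qc_pass: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class ConsensusDeletion:
    chrom: str
    start: int
    end: int
    members: list = field(default_factory=list)   # (sample, start, end)
    carriers: set = field(default_factory=set)
    frequency: float = float("nan")
    genes: list = field(default_factory=list)


def reciprocal_overlap(a, b) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for disjoint or cross-chromosome.

    ``a`` and ``b`` are (chrom, start, end) triples or objects with those
    attributes; intervals are half-open so adjacency does not overlap.
    """
    ca, sa, ea = _interval(a)
    cb, sb, eb = _interval(b)
    if ca != cb:
        return 0.0
    ov = min(ea, eb) - max(sa, sb)
    if ov <= 0:
        return 0.0
    return min(ov / (ea - sa), ov / (eb - sb))


def _interval(x):
    if isinstance(x, tuple):
        return x[0], x[1], x[2]
    return x.chrom, x.start, x.end


def intersect_callers(calls, min_ro: float = 0.20, callers=None):
    """Two-caller consensus within each sample.

    Keeps a call when the other caller has a call with reciprocal overlap
    >= ``min_ro`` in the same sample, dropping pairs where both members
    failed QC.  The representative interval of each supported pair is the
    union of the two members (conservative for exon annotation).  Returns a
    list of DeletionCall-like consensus records (caller id "consensus").
    """
    calls = list(calls)
    seen_callers = sorted({c.caller for c in calls})
    if callers is None:
        callers = seen_callers
    if len(callers) != 2:
        raise ValueError(f"exactly two callers required, saw {callers}")
    unknown = set(seen_callers) - set(callers)
    if unknown:
        raise ValueError(f"unknown caller id(s): {sorted(unknown)}")
    a_name, b_name = callers
    out = []
    by_sample: dict[str, list] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    for sample in sorted(by_sample):
        group = by_sample[sample]
        a_calls = [c for c in group if c.caller == a_name]
        b_calls = [c for c in group if c.caller == b_name]
        for ca in a_calls:
            for cb in b_calls:
                if reciprocal_overlap(ca, cb) >= min_ro:
                    if not ca.qc_pass and not cb.qc_pass:
                        continue
                    out.append(DeletionCall(
                        sample=sample, caller="consensus", chrom=ca.chrom,
                        start=min(ca.start, cb.start), end=max(ca.end, cb.end),
                        qc_pass=True,
                    ))
    # deduplicate identical union intervals per sample
    uniq = {}
    for c in out:
        uniq[(c.sample, c.chrom, c.start, c.end)] = c
    return list(uniq.values())


def exclude_benign(calls, benign_regions, min_ro: float = 0.20):
    """Drop calls reciprocally overlapping (>= min_ro) any benign region.

    ``benign_regions``: iterable of (chrom, start, end).
    """
    regions = [(_interval(r)) for r in benign_regions]
    out = []
    for c in calls:
        if any(reciprocal_overlap(c, r) >= min_ro for r in regions):
            continue
        out.append(c)
    return out


def merge_across_samples(calls, min_ro: float = 0.50, cohort_size: int | None = None):
    """Single-linkage clustering of per-sample events at RO >= min_ro.

    Each cluster becomes one ConsensusDeletion spanning the min/max member
    coordinates, with the carrier sample set and (if ``cohort_size`` given)
    the cohort carrier frequency.  Clustering is independent of input
    order.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            # sorted by (chrom, start): nothing further can overlap i
            if calls[j].chrom != calls[i].chrom or calls[j].start >= calls[i].end:
                break
            if reciprocal_overlap(calls[i], calls[j]) >= min_ro:
                graph.add_edge(i, j)
    events = []
    for comp in nx.connected_components(graph):
        members = [calls[i] for i in sorted(comp)]
        carriers = {c.sample for c in members}
        ev = ConsensusDeletion(
            chrom=members[0].chrom,
            start=min(c.start for c in members),
            end=max(c.end for c in members),
            members=[(c.sample, c.start, c.end) for c in members],
            carriers=carriers,
        )
        if cohort_size:
            ev.frequency = len(carriers) / cohort_size
        events.append(ev)
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return events


def filter_frequency_and_exons(
    events,
    cohort_size: int,
    exons: pd.DataFrame,
    max_freq: float = 1e-3,
):
    """Retain rare events (carrier frequency strictly < max_freq) that
    intersect >= 1 exon; annotates events with the overlapped gene symbols.

    ``exons``: DataFrame with columns gene, chrom, start, end (half-open).
    """
    out = []
    for ev in events:
        freq = len(ev.carriers) / cohort_size
        ev.frequency = freq
        if not freq < max_freq:
            continue
        sub = exons.loc[exons["chrom"] == ev.chrom]
        genes = sorted(set(
            sub.loc[(sub["start"] < ev.end) & (sub["end"] > ev.start), "gene"]
        ))
        if not genes:
            continue
        ev.genes = genes
        out.append(ev)
    return out


def deletion_burden(
    events,
    samples: pd.DataFrame,
    m_bonferroni: int | None = None,
    exclude_gene: str | None = None,
) -> pd.DataFrame:
    """Per-gene deletion carrier counts and one-tailed Fisher tests.

    A subject with several events over one gene counts once.  With
    ``exclude_gene`` set, subjects carrying a deletion over that gene are
    removed before counting (the re-run after removing carriers at the
    dominant locus).  ``m_bonferroni`` defaults to the number of genes
    tested.
    """
    status = samples.set_index("sample_id")["status"]
    excluded: set = set()
    if exclude_gene is not None:
        for ev in events:
            if exclude_gene in ev.genes:
                excluded |= ev.carriers
    analysed = [s for s in samples["sample_id"] if s not in excluded]
    is_case = {s: status[s] == "case" for s in analysed}
    n_case = sum(is_case.values())
    n_control = len(analysed) - n_case

    per_gene: dict[str, set] = {}
    for ev in events:
        for gene in ev.genes:
            if exclude_gene is not None and gene == exclude_gene:
                continue
            per_gene.setdefault(gene, set()).update(
                s for s in ev.carriers if s not in excluded
            )
    rows = []
    genes = sorted(per_gene)
    m = m_bonferroni if m_bonferroni is not None else max(len(genes), 1)
    for gene in genes:
        carriers = per_gene[gene]
        a = sum(1 for s in carriers if is_case.get(s))
        c = sum(1 for s in carriers if is_case.get(s) is False)
        if a + c == 0:
            continue
        t = CarrierTable(gene, "deletion", a, n_case - a, c, n_control - c)
        p = fisher_one_tailed(t)
        rows.append({
            "gene": gene, "mode": "deletion",
            "case_carriers": a, "case_noncarriers": n_case - a,
            "control_carriers": c, "control_noncarriers": n_control - c,
            "p_raw": p, "p_adjusted": min(1.0, m * p), "m_bonferroni": m,
            "excluded_subjects": len(excluded),
        })
    return pd.DataFrame(rows, columns=[
        "gene", "mode", "case_carriers", "case_noncarriers", "control_carriers",
        "control_noncarriers", "p_raw", "p_adjusted", "m_bonferroni",
        "excluded_subjects",
    ])
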
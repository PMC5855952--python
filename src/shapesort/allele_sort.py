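"""Allele-specific sorting of aligned reads at a single variant site.

When both alleles of a transcript are chemically probed in the same tube,
the reads can be partitioned afterwards by the base observed at the variant
position, giving two reactivity profiles measured under identical
conditions.  Only read pairs in which at least one mate spans the variant
are informative; pairs whose covering base matches neither allele, is a
deletion, or fails the base-quality threshold are set aside as ``other``
rather than rescued, and pairs whose two mates disagree are discarded the
same way.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .mapsim import VariantSpec

__all__ = [
    "AlleleAssignment",
    "assign_allele",
    "group_pairs",
    "sort_reads",
    "estimate_allele_fraction",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_BASE_QUALITY = 20

CALLS = ("ref", "alt", "other", "unassigned")


@dataclass(frozen=True)
class AlleleAssignment:
    """The allele call for one read pair at the variant site.

    ``call`` is ``unassigned`` when no mate covers the variant position,
    ``other`` when the covering evidence is a non-allelic base, a gap, a
    low-quality call, or a mate conflict.
    """

    read_id: str
    call: str
    evidence_base: str | None = None
    evidence_quality: int | None = None


def _base_at(read, position: int):
    """Observed (base, quality) of ``read`` at reference ``position``.

    Returns None if the read does not cover the position; base is None for
    a deletion spanning the site.
    """
    if read.is_unmapped:
        return None
    if not (read.reference_start <= position < read.reference_end):
        return None
    for qpos, rpos in read.get_aligned_pairs():
        if rpos == position:
            if qpos is None:  # deletion over the site
                return (None, None)
            return (read.query_sequence[qpos].upper(),
                    read.query_qualities[qpos] if read.query_qualities is not None else None)
    return None


def assign_allele(
    read_pair,
    variant: VariantSpec,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> AlleleAssignment:
    """Assign one read (or mate pair) to an allele at the variant site.

    ``read_pair`` is a single :class:`pysam.AlignedSegment` or a sequence of
    mates sharing a query name.  If exactly one mate covers the variant its
    base decides; if both cover and agree that base decides; conflicting
    mates give ``other``.  Quality below ``min_base_quality`` and deletions
    give ``other``; no coverage gives ``unassigned``.
    """
    reads = [read_pair] if hasattr(read_pair, "query_name") else list(read_pair)
    if not reads:
        raise ValueError("empty read pair")
    read_id = reads[0].query_name
    if all(r.is_unmapped for r in reads):
        logger.warning("unmapped read pair %s", read_id)
        return AlleleAssignment(read_id, "unassigned")
    ref_len = reads[0].header.get_reference_length(reads[0].reference_name) \
        if reads[0].header is not None and not reads[0].is_unmapped else None
    if ref_len is not None and not 0 <= variant.position < ref_len:
        raise ValueError(f"variant position {variant.position} outside reference")

    evidence = [obs for r in reads if (obs := _base_at(r, variant.position)) is not None]
    if not evidence:
        return AlleleAssignment(read_id, "unassigned")

    bases = {b for b, _ in evidence}
    if len(bases) > 1:  # mate conflict
        return AlleleAssignment(read_id, "other")
    base, qual = evidence[0]
    if base is None:  # deletion spanning the site
        return AlleleAssignment(read_id, "other")
    qual = min((q for _, q in evidence if q is not None), default=None)
    if qual is not None and qual < min_base_quality:
        return AlleleAssignment(read_id, "other", base, qual)
    if base == variant.ref_base:
        call = "ref"
    elif base == variant.alt_base:
        call = "alt"
    else:
        call = "other"
    return AlleleAssignment(read_id, call, base, qual)


def group_pairs(reads) -> "OrderedDict[str, list]":
    """Group reads into pairs by query name, preserving first-seen order."""
    pairs: OrderedDict[str, list] = OrderedDict()
    for r in reads:
        pairs.setdefault(r.query_name, []).append(r)
    return pairs


def sort_reads(
    reads,
    variant: VariantSpec,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
):
    """Partition reads into per-allele read sets.

    Returns ``(ref_reads, alt_reads, counts, assignments)``: the two
    disjoint allele read lists (``other``/``unassigned`` pairs are
    excluded from both), a Counter of calls by read pair, and the
    per-pair :class:`AlleleAssignment` list.  Duplicate query names are
    treated as mates of one pair and assigned once.
    """
    pairs = group_pairs(reads)
    ref_reads, alt_reads = [], []
    counts: Counter = Counter({c: 0 for c in CALLS})
    assignments = []
    for qname, mates in pairs.items():
        a = assign_allele(mates, variant, min_base_quality)
        assignments.append(a)
        counts[a.call] += 1
        if a.call == "ref":
            ref_reads.extend(mates)
        elif a.call == "alt":
            alt_reads.extend(mates)
    return ref_reads, alt_reads, counts, assignments


def estimate_allele_fraction(counts) -> tuple[float, tuple[float, float]]:
    """Alternate-allele fraction alt/(ref+alt) with a 95% Wilson interval.

    Quality-controls the mutagenesis efficiency / spike-in ratio.  Raises
    on zero informative (ref+alt) reads.
    """
    n_ref, n_alt = counts["ref"], counts["alt"]
    n = n_ref + n_alt
    if n == 0:
        raise ValueError("no informative reads: allele fraction undefined")
    frac = n_alt / n
    lo, hi = proportion_confint(n_alt, n, alpha=0.05, method="wilson")
    return frac, (float(lo), float(hi))


def counts_table(counts) -> pd.DataFrame:
    return pd.DataFrame({"call": list(CALLS), "n_pairs": [counts[c] for c in CALLS]})
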
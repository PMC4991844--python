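"""Paired-end amplicon pipeline: merge, demultiplex, filter, dereplicate,
cluster.

The stages mirror a standard tag-based metabarcoding workflow:

1. merge read pairs over their best ungapped 3' overlap;
2. demultiplex by exact 8-nt tag + primer match at both ends (reads with
   any N, reads not matching perfectly, and tag-ambiguous reads are
   discarded), then trim tags and primers;
3. quality filter (default: mean Phred >= 30) and length filter
   (>= 100 bp after trimming);
4. dereplicate into unique sequences with per-sample abundances;
5. greedy centroid clustering into OTUs at 98% identity, scanning
   uniques in abundance order.

Read conservation — ``reads_in == reads_out + sum(discards)`` — is
asserted by the runner at every stage.  Chimera removal is not
performed; :func:`run_pipeline` exposes a hook for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from anserdiet.io_core import (
    IUPAC,
    MAX_PHRED33,
    RunConfig,
    SampleSheet,
    SeqRecord,
    log_stage,
    revcomp,
)


@dataclass
class MergedRead:
    """A merged read pair; ``sample_id`` is set only by demultiplexing."""

    id: str
    sequence: str
    quality: list[int]
    sample_id: str | None = None
    provenance: tuple[str, str] | None = None

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# stage 1: merging


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pairs(
    fwd_reads: Sequence[SeqRecord],
    rev_reads: Sequence[SeqRecord],
    config: RunConfig,
) -> tuple[list[MergedRead], list[str]]:
    """Merge positionally paired reads over their best ungapped overlap.

    The reverse read is reverse-complemented; candidate overlaps of at
    least ``merge_min_overlap`` bases are scored and the one with the
    most matching bases (ties: the longest) is taken, provided its
    mismatch fraction is <= ``merge_max_mismatch_frac``.  In the overlap
    the higher-quality base is called; the posterior quality is the
    maximum of the two scores when the calls agree and their absolute
    difference when they conflict, capped at 41.

    Returns (merged reads, ids of rejected pairs).
    """
    if len(fwd_reads) != len(rev_reads):
        raise ValueError(
            f"unequal file lengths: {len(fwd_reads)} forward vs "
            f"{len(rev_reads)} reverse reads"
        )
    merged: list[MergedRead] = []
    rejects: list[str] = []
    for f, r in zip(fwd_reads, rev_reads):
        if f.quality is None or r.quality is None:
            raise ValueError("merging requires FASTQ input with qualities")
        rc_seq = revcomp(r.sequence)
        rc_qual = r.quality[::-1]
        m = _merge_one(f.sequence, f.quality, rc_seq, rc_qual, config)
        if m is None:
            rejects.append(f.id)
            continue
        seq, qual = m
        merged.append(
            MergedRead(f.id, seq, qual, provenance=(f.id, r.id))
        )
    log_stage("merge_pairs", pairs_in=len(fwd_reads), merged=len(merged),
              rejected=len(rejects))
    return merged, rejects


def _merge_one(
    fseq: str,
    fqual: Sequence[int],
    rseq: str,
    rqual: Sequence[int],
    config: RunConfig,
) -> tuple[str, list[int]] | None:
    fa, ra = _encode(fseq), _encode(rseq)
    max_o = min(len(fa), len(ra))
    best: tuple[int, int] | None = None  # (matches, overlap)
    for o in range(max_o, max(config.merge_min_overlap, 1) - 1, -1):
        mm = int((fa[len(fa) - o:] != ra[:o]).sum())
        if mm / o > config.merge_max_mismatch_frac:
            continue
        matches = o - mm
        if best is None or matches > best[0]:
            best = (matches, o)
    if best is None:
        return None
    o = best[1]
    off = len(fseq) - o
    ov_seq: list[str] = []
    ov_qual: list[int] = []
    for k in range(o):
        bf, br = fseq[off + k], rseq[k]
        qf, qr = fqual[off + k], rqual[k]
        if bf == br:
            ov_seq.append(bf)
            ov_qual.append(min(max(qf, qr), MAX_PHRED33))
        else:
            ov_seq.append(bf if qf >= qr else br)
            ov_qual.append(min(abs(qf - qr), MAX_PHRED33))
    seq = fseq[:off] + "".join(ov_seq) + rseq[o:]
    qual = list(fqual[:off]) + ov_qual + list(rqual[o:])
    return seq, qual


# ---------------------------------------------------------------------------
# stage 2: demultiplexing


@dataclass
class DiscardLog:
    """Per-category discard counts; categories are mutually exclusive."""

    ambiguous_base: int = 0   # read contains an N
    no_tag_match: int = 0     # no sample's tag+primer pattern fits
    ambiguous_tag: int = 0    # read fits two or more samples
    empty_insert: int = 0     # nothing left after trimming

    @property
    def total(self) -> int:
        return (self.ambiguous_base + self.no_tag_match
                + self.ambiguous_tag + self.empty_insert)


def _iupac_match(pattern: str, segment: str) -> bool:
    return len(pattern) == len(segment) and all(
        b in IUPAC[p] for p, b in zip(pattern, segment)
    )


def demultiplex(
    reads: Sequence[MergedRead], sheet: SampleSheet
) -> tuple[list[MergedRead], DiscardLog]:
    """Assign merged reads to samples by exact tag + primer match.

    A read is assigned to sample *s* iff it begins with
    ``s.fwd_tag + s.fwd_primer`` and ends with
    ``revcomp(s.rev_primer) + revcomp(s.rev_tag)``; tags match exactly
    and primers by their IUPAC degeneracy sets.  Reads containing any N
    are discarded first.  Tags and primers are then trimmed from both
    ends.  A read matching two samples (possible only with a malformed
    sheet) is discarded as ambiguous.
    """
    patterns = []
    for row in sheet:
        head_tag = row.fwd_tag
        head_primer = row.fwd_primer
        tail_primer = revcomp(row.rev_primer)
        tail_tag = revcomp(row.rev_tag)
        patterns.append((row.sample_id, head_tag, head_primer,
                         tail_primer, tail_tag))
    assigned: list[MergedRead] = []
    log = DiscardLog()
    for read in reads:
        seq = read.sequence
        if "N" in seq:
            log.ambiguous_base += 1
            continue
        hits = []
        for sample_id, htag, hprimer, tprimer, ttag in patterns:
            head_len = len(htag) + len(hprimer)
            tail_len = len(tprimer) + len(ttag)
            if len(seq) < head_len + tail_len:
                continue
            if not seq.startswith(htag):
                continue
            if not _iupac_match(hprimer, seq[len(htag):head_len]):
                continue
            if not seq.endswith(ttag):
                continue
            tp_start = len(seq) - tail_len
            if not _iupac_match(tprimer, seq[tp_start:tp_start + len(tprimer)]):
                continue
            hits.append((sample_id, head_len, tail_len))
        if not hits:
            log.no_tag_match += 1
            continue
        if len(hits) > 1:
            log.ambiguous_tag += 1
            continue
        sample_id, head_len, tail_len = hits[0]
        insert = seq[head_len:len(seq) - tail_len]
        if not insert:
            log.empty_insert += 1
            continue
        assigned.append(
            MergedRead(
                read.id,
                insert,
                read.quality[head_len:len(read.quality) - tail_len],
                sample_id=sample_id,
                provenance=read.provenance,
            )
        )
    log_stage("demultiplex", reads_in=len(reads), assigned=len(assigned),
              discarded=log.total)
    return assigned, log


# ---------------------------------------------------------------------------
# stage 3: quality / length filter


def expected_errors(quality: Sequence[int]) -> float:
    return float(sum(10.0 ** (-q / 10.0) for q in quality))


def quality_filter(
    reads: Sequence[MergedRead], config: RunConfig
) -> tuple[list[MergedRead], dict[str, int]]:
    """Keep reads with length >= min_len and passing the quality rule.

    ``qual_mode`` selects the rule: ``mean`` (default) keeps reads whose
    mean Phred is >= ``min_qual``; ``min`` requires every base >=
    ``min_qual``; ``ee`` keeps reads with at most 1.0 expected errors.
    Boundary semantics: a read exactly ``min_len`` long is kept.
    """
    kept: list[MergedRead] = []
    rejected = {"short": 0, "low_quality": 0}
    for read in reads:
        if read.quality is None:
            raise ValueError(f"read {read.id}: no quality track")
        if len(read) < config.min_len:
            rejected["short"] += 1
            continue
        q = read.quality
        if config.qual_mode == "mean":
            ok = (sum(q) / len(q)) >= config.min_qual
        elif config.qual_mode == "min":
            ok = min(q) >= config.min_qual
        else:  # ee
            ok = expected_errors(q) <= 1.0
        if not ok:
            rejected["low_quality"] += 1
            continue
        kept.append(read)
    log_stage("quality_filter", reads_in=len(reads), kept=len(kept),
              **rejected)
    return kept, rejected


# ---------------------------------------------------------------------------
# stage 4: dereplication


@dataclass
class UniqueSeq:
    sequence: str
    abundance: int
    per_sample: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_sample and self.abundance != sum(self.per_sample.values()):
            raise ValueError("abundance != sum of per-sample counts")


def dereplicate(reads: Sequence[MergedRead]) -> list[UniqueSeq]:
    """Exact-sequence grouping, sorted by abundance descending then
    lexicographically by sequence."""
    per_seq: dict[str, dict[str, int]] = {}
    for read in reads:
        if read.sample_id is None:
            raise ValueError(f"read {read.id}: sample_id not set")
        counts = per_seq.setdefault(read.sequence, {})
        counts[read.sample_id] = counts.get(read.sample_id, 0) + 1
    uniques = [
        UniqueSeq(seq, sum(counts.values()), dict(sorted(counts.items())))
        for seq, counts in per_seq.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    log_stage("dereplicate", reads_in=len(reads), uniques=len(uniques))
    return uniques


# ---------------------------------------------------------------------------
# stage 5: greedy OTU clustering


@dataclass
class Otu:
    otu_id: str
    representative: str
    members: list[UniqueSeq] = field(default_factory=list)

    @property
    def per_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for s, c in m.per_sample.items():
                out[s] = out.get(s, 0) + c
        return dict(sorted(out.items()))

    @property
    def abundance(self) -> int:
        return sum(m.abundance for m in self.members)


_CLUSTER_ALIGNER = Align.PairwiseAligner()
_CLUSTER_ALIGNER.mode = "global"
_CLUSTER_ALIGNER.match_score = 1
_CLUSTER_ALIGNER.mismatch_score = -2
_CLUSTER_ALIGNER.open_gap_score = -5
_CLUSTER_ALIGNER.extend_gap_score = -2


def cluster_identity(a: str, b: str) -> float:
    """Identity = matches / alignment columns of a global alignment with
    end gaps penalized.

    For equal-length pairs whose ungapped identity already reaches 90%
    the ungapped alignment is provably optimal under this scoring (any
    gap pair costs more than the mismatches it could save), so the
    column comparison is used directly.
    """
    if a == b:
        return 1.0
    if len(a) == len(b):
        ungapped = sum(x == y for x, y in zip(a, b)) / len(a)
        if ungapped >= 0.90:
            return ungapped
    aln = _CLUSTER_ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_otus(uniques: Sequence[UniqueSeq], config: RunConfig) -> list[Otu]:
    """Greedy centroid clustering at ``otu_identity``.

    Uniques are scanned in the order produced by :func:`dereplicate`
    (abundance descending); each joins the first existing centroid at
    identity >= the threshold, else founds a new OTU.  The representative
    is the founding (highest-abundance) member.
    """
    otus: list[Otu] = []
    for u in uniques:
        placed = False
        for otu in otus:
            if cluster_identity(otu.representative, u.sequence) >= config.otu_identity:
                otu.members.append(u)
                placed = True
                break
        if not placed:
            otus.append(Otu(f"OTU{len(otus) + 1:04d}", u.sequence, [u]))
    log_stage("cluster_otus", uniques_in=len(uniques), otus=len(otus))
    return otus


def audit_otus(otus: Sequence[Otu], config: RunConfig) -> None:
    """Post-hoc check: every member is within the identity threshold of
    its representative."""
    for otu in otus:
        for m in otu.members:
            ident = cluster_identity(otu.representative, m.sequence)
            if ident < config.otu_identity:
                raise AssertionError(
                    f"{otu.otu_id}: member at identity {ident:.4f} < "
                    f"{config.otu_identity}"
                )


# ---------------------------------------------------------------------------
# runner


@dataclass
class PipelineResult:
    otus: list[Otu]
    otu_table: pd.DataFrame          # otu_id x sample_id read counts
    per_sample: pd.DataFrame         # Table-5-style stage accounting
    accounting: dict[str, int]
    merge_rejects: list[str]
    discards: DiscardLog
    filter_rejects: dict[str, int]


def otu_table(otus: Sequence[Otu], samples: Sequence[str]) -> pd.DataFrame:
    data = {
        otu.otu_id: [otu.per_sample.get(s, 0) for s in samples]
        for otu in otus
    }
    return pd.DataFrame(data, index=list(samples)).T


def run_pipeline(
    fwd_reads: Sequence[SeqRecord],
    rev_reads: Sequence[SeqRecord],
    sheet: SampleSheet,
    config: RunConfig,
    chimera_hook: Callable[[list[UniqueSeq]], list[UniqueSeq]] | None = None,
) -> PipelineResult:
    """Run all stages and assert read conservation after each.

    ``chimera_hook`` may replace the unique-sequence list before
    clustering (chimera detection is otherwise not performed).  Note that
    reads can be attributed to samples only after demultiplexing, so the
    per-sample accounting starts at the assignment stage.
    """
    n_pairs = len(fwd_reads)
    merged, merge_rejects = merge_pairs(fwd_reads, rev_reads, config)
    assert n_pairs == len(merged) + len(merge_rejects)

    assigned, discards = demultiplex(merged, sheet)
    assert len(merged) == len(assigned) + discards.total

    kept, filter_rejects = quality_filter(assigned, config)
    assert len(assigned) == len(kept) + sum(filter_rejects.values())

    uniques = dereplicate(kept)
    assert len(kept) == sum(u.abundance for u in uniques)
    if chimera_hook is not None:
        uniques = chimera_hook(uniques)

    otus = cluster_otus(uniques, config)
    assert sum(u.abundance for u in uniques) == sum(o.abundance for o in otus)

    samples = [row.sample_id for row in sheet]
    table = otu_table(otus, samples)
    kept_by_sample = {
        s: sum(1 for r in kept if r.sample_id == s) for s in samples
    }
    assigned_by_sample = {
        s: sum(1 for r in assigned if r.sample_id == s) for s in samples
    }
    uniques_by_sample = {
        s: sum(1 for u in uniques if u.per_sample.get(s, 0) > 0)
        for s in samples
    }
    otus_by_sample = {
        s: int((table[s] > 0).sum()) for s in samples
    }
    per_sample = pd.DataFrame(
        {
            "sample": samples,
            "pair_end": [assigned_by_sample[s] for s in samples],
            "retained": [kept_by_sample[s] for s in samples],
            "uniques": [uniques_by_sample[s] for s in samples],
            "otus": [otus_by_sample[s] for s in samples],
        }
    )
    accounting = {
        "pairs_in": n_pairs,
        "merged": len(merged),
        "merge_rejected": len(merge_rejects),
        "assigned": len(assigned),
        "demux_discarded": discards.total,
        "kept": len(kept),
        "filter_short": filter_rejects["short"],
        "filter_low_quality": filter_rejects["low_quality"],
        "uniques": len(uniques),
        "otus": len(otus),
    }
    return PipelineResult(
        otus=otus,
        otu_table=table,
        per_sample=per_sample,
        accounting=accounting,
        merge_rejects=merge_rejects,
        discards=discards,
        filter_rejects=filter_rejects,
    )
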
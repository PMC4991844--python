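"""Local barcode reference library.

Records are collapsed into *resolution groups* by exact sequence
identity (after upper-casing): species sharing a barcode sequence cannot
be told apart by that marker, so the group's assignable rank is the
lowest rank containing all of its species.  Per-family species and
unique-sequence counts summarize the discriminating power of the marker
across the sampled flora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from anserdiet.io_core import (
    ParseError,
    SeqRecord,
    Taxon,
    TaxonomyMap,
    logger,
    write_fasta,
    write_table,
)

MAX_N_FRACTION = 0.05


@dataclass(frozen=True)
class RefRecord:
    seq_id: str
    sequence: str
    family: str
    genus: str
    species: str

    @property
    def taxon(self) -> Taxon:
        return Taxon(self.family, self.genus, self.species)


@dataclass
class ResolutionGroup:
    """Records sharing one exact sequence, with their assignable rank."""

    group_id: str
    sequence: str
    records: list[RefRecord]

    @property
    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    @property
    def rank(self) -> str:
        return resolution_of(self.records)

    @property
    def taxon(self) -> str:
        """Name at the assignable rank ('' above family)."""
        rank = self.rank
        if rank == "above_family":
            return ""
        return getattr(self.records[0], rank)


def resolution_of(records: list[RefRecord]) -> str:
    """Assignable rank of a set of records sharing one sequence.

    species if one species; genus if several species of one genus;
    family if several genera of one family; above_family otherwise.
    Merging groups can only coarsen the rank (monotonicity).
    """
    if not records:
        raise ValueError("empty resolution group")
    species = {r.species for r in records}
    if len(species) == 1:
        return "species"
    genera = {r.genus for r in records}
    if len(genera) == 1:
        return "genus"
    families = {r.family for r in records}
    if len(families) == 1:
        return "family"
    return "above_family"


@dataclass
class ReferenceLibrary:
    records: list[RefRecord]
    groups: list[ResolutionGroup]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def taxonomy(self) -> TaxonomyMap:
        tax = TaxonomyMap()
        for r in self.records:
            tax[r.seq_id] = r.taxon
        return tax

    def record(self, seq_id: str) -> RefRecord:
        return self._by_id[seq_id]

    @property
    def _by_id(self) -> dict[str, RefRecord]:
        return {r.seq_id: r for r in self.records}

    def group_of(self, seq_id: str) -> ResolutionGroup:
        for g in self.groups:
            if seq_id in g.seq_ids:
                return g
        raise KeyError(seq_id)

    def family_counts(self) -> pd.DataFrame:
        """Per-family number of species and of unique sequences."""
        rows = []
        families = sorted({r.family for r in self.records})
        for fam in families:
            fam_records = [r for r in self.records if r.family == fam]
            rows.append(
                {
                    "family": fam,
                    "n_species": len({r.species for r in fam_records}),
                    "n_sequences": len({r.sequence for r in fam_records}),
                }
            )
        return pd.DataFrame(rows, columns=["family", "n_species", "n_sequences"])

    def write(self, outdir) -> None:
        """Library archive: normalized FASTA + groups TSV + family counts."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SeqRecord(r.seq_id, r.sequence) for r in self.records],
            outdir / "reference.fasta",
        )
        self.taxonomy.write(outdir / "taxonomy.tsv")
        groups_df = pd.DataFrame(
            [
                {
                    "group_id": g.group_id,
                    "seq_ids": ",".join(g.seq_ids),
                    "rank": g.rank,
                    "taxon": g.taxon,
                }
                for g in self.groups
            ],
            columns=["group_id", "seq_ids", "rank", "taxon"],
        )
        write_table(groups_df, outdir / "groups.tsv")
        write_table(self.family_counts(), outdir / "family_counts.tsv")


def build_library(
    records: list[SeqRecord], taxonomy: TaxonomyMap
) -> ReferenceLibrary:
    """Validate reference sequences and collapse exact duplicates.

    Every FASTA id must appear in the taxonomy map.  Sequences with an N
    fraction above 5% are rejected with a warning (kept in
    ``library.rejected``).  Collapsing is by exact string equality only;
    a sequence that is a strict prefix of another is *not* collapsed but
    logged, since differing amplicon trim lengths can cause it.
    """
    missing = [r.id for r in records if r.id not in taxonomy]
    if missing:
        raise ParseError(f"ids missing from taxonomy map: {missing}")
    kept: list[RefRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        seq = rec.sequence.upper().replace("U", "T")
        n_frac = seq.count("N") / len(seq)
        if n_frac > MAX_N_FRACTION:
            reason = f"N fraction {n_frac:.3f} > {MAX_N_FRACTION}"
            logger.warning("build_library: rejecting %s: %s", rec.id, reason)
            rejected.append((rec.id, reason))
            continue
        t = taxonomy[rec.id]
        kept.append(RefRecord(rec.id, seq, t.family, t.genus, t.species))

    by_seq: dict[str, list[RefRecord]] = {}
    for r in kept:
        by_seq.setdefault(r.sequence, []).append(r)
    # deterministic group order: by first seq_id of the group, sorted
    groups = [
        ResolutionGroup(f"G{idx + 1:04d}", seq, members)
        for idx, (seq, members) in enumerate(
            sorted(by_seq.items(), key=lambda kv: min(r.seq_id for r in kv[1]))
        )
    ]
    seqs = sorted(by_seq)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            if len(a) != len(b) and (b.startswith(a) or a.startswith(b)):
                logger.warning(
                    "build_library: sequences differing only by terminal "
                    "length present (not collapsed)"
                )
    return ReferenceLibrary(records=kept, groups=groups, rejected=rejected)
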
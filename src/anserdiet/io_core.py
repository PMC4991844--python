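"""Readers/writers for external formats, run configuration and logging.

All tables are tab-separated with a single header row; lines starting with
``#`` are comments.  FASTQ quality strings are Phred+33 only — the modern
default; +64-encoded input is rejected by a heuristic (any decoded score
above 41) with an explicit error.  Percentages are kept as floats
internally and rounded only at serialization: two decimals, half away
from zero.
"""

from __future__ import annotations

import decimal
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("anserdiet")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC nucleotide codes and the base sets they match.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format or an invariant."""


@dataclass
class SeqRecord:
    """A nucleotide sequence with an optional Phred quality track."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequences are upper-cased and U is mapped to T.  Duplicate ids, empty
    sequences, characters outside {A,C,G,T,N} (after normalization) and
    structural problems raise :class:`ParseError` naming the offending
    line.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq))
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ParseError(
                f"{path.name}: record {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        records.append(SeqRecord(rec.id, seq))
    logger.info("read_fasta: %s: %d records", path.name, len(records))
    return records


def _prescan_fasta(path: Path) -> None:
    """Structural scan so errors can name a line number."""
    seen: set[str] = set()
    header_line = None
    has_seq = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    raise ParseError(
                        f"{path.name}:{header_line}: header with empty sequence"
                    )
                ident = line[1:].split()[0] if len(line) > 1 else ""
                if not ident:
                    raise ParseError(f"{path.name}:{lineno}: malformed header")
                if ident in seen:
                    raise ParseError(
                        f"{path.name}:{lineno}: duplicate id {ident!r}"
                    )
                seen.add(ident)
                header_line, has_seq = lineno, False
            else:
                if header_line is None:
                    raise ParseError(
                        f"{path.name}:{lineno}: sequence data before any header"
                    )
                has_seq = True
    if header_line is not None and not has_seq:
        raise ParseError(f"{path.name}:{header_line}: header with empty sequence")
    if header_line is None and seen == set():
        # empty file is allowed (empty library)
        return


#: Highest Phred score emitted by Phred+33 Illumina chemistry; anything
#: larger indicates a +64-encoded file.
MAX_PHRED33 = 41


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a Phred+33 FASTQ file.

    Qualities are decoded to integer scores.  Truncated records and
    sequence/quality length mismatches raise :class:`ParseError`; a score
    above 41 is taken as evidence of Phred+64 encoding and rejected.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            if quals and max(quals) > MAX_PHRED33:
                raise ParseError(
                    f"{path.name}: record {rec.id!r} has Phred score "
                    f"{max(quals)} > {MAX_PHRED33}; input looks Phred+64 "
                    "encoded, only Phred+33 is accepted"
                )
            if rec.id in seen:
                raise ParseError(f"{path.name}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, _normalize(str(rec.seq)), list(quals)))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path.name}: {exc}") from exc
    logger.info("read_fastq: %s: %d records", path.name, len(records))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality track")
            qual = "".join(chr(min(q, MAX_PHRED33) + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    group: str
    fwd_tag: str
    rev_tag: str
    fwd_primer: str
    rev_primer: str


TAG_LENGTH = 8


@dataclass
class SampleSheet:
    """Per-sample 8-nt tags and fusion primers for demultiplexing."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ParseError("sample sheet: duplicate sample_id")
        pairs = [(r.fwd_tag, r.rev_tag) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ParseError("sample sheet: duplicate (fwd_tag, rev_tag) pair")
        for r in self.rows:
            for tag in (r.fwd_tag, r.rev_tag):
                if len(tag) != TAG_LENGTH or set(tag) - set("ACGT"):
                    raise ParseError(
                        f"sample {r.sample_id}: tag {tag!r} must be "
                        f"{TAG_LENGTH} nt over ACGT"
                    )
            for primer in (r.fwd_primer, r.rev_primer):
                if not primer or set(primer) - set(IUPAC):
                    raise ParseError(
                        f"sample {r.sample_id}: primer {primer!r} is not an "
                        "IUPAC nucleotide string"
                    )

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def groups(self) -> dict[str, str]:
        """sample_id -> group label."""
        return {r.sample_id: r.group for r in self.rows}

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = read_table(path)
        required = ["sample_id", "group", "fwd_tag", "rev_tag",
                    "fwd_primer", "rev_primer"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"sample sheet: missing columns {missing}")
        rows = [
            SampleRow(*(str(row[c]).strip().upper() if c not in
                        ("sample_id", "group") else str(row[c]).strip()
                        for c in required))
            for _, row in df.iterrows()
        ]
        return cls(rows)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        write_table(df, path)


# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class Taxon:
    family: str
    genus: str = ""
    species: str = ""


class TaxonomyMap(dict):
    """seq_id -> :class:`Taxon`; empty genus/species denote coarser knowledge."""

    def __setitem__(self, key: str, value: Taxon) -> None:
        if value.species and not value.genus:
            raise ParseError(f"{key}: species given without genus")
        if value.genus and not value.family:
            raise ParseError(f"{key}: genus given without family")
        if not value.family:
            raise ParseError(f"{key}: family must be non-empty")
        super().__setitem__(key, value)

    @classmethod
    def read(cls, path: str | Path) -> "TaxonomyMap":
        df = read_table(path)
        required = ["seq_id", "family", "genus", "species"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"taxonomy map: missing columns {missing}")
        tax = cls()
        for _, row in df.iterrows():
            sid = str(row["seq_id"]).strip()
            if sid in tax:
                raise ParseError(f"taxonomy map: duplicate seq_id {sid!r}")
            tax[sid] = Taxon(
                family=_cell(row["family"]),
                genus=_cell(row["genus"]),
                species=_cell(row["species"]),
            )
        return tax

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(k, t.family, t.genus, t.species) for k, t in sorted(self.items())],
            columns=["seq_id", "family", "genus", "species"],
        )
        write_table(df, path)

    def species_index(self) -> dict[str, Taxon]:
        """species name -> Taxon (first occurrence wins)."""
        out: dict[str, Taxon] = {}
        for t in self.values():
            if t.species and t.species not in out:
                out[t.species] = t
        return out


def _cell(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v).strip()


def read_microhistology(path: str | Path) -> pd.DataFrame:
    """Microhistology table: columns group, taxon, rank, fm_percent."""
    df = read_table(path)
    required = ["group", "taxon", "rank", "fm_percent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"microhistology table: missing columns {missing}")
    df = df.copy()
    df["fm_percent"] = df["fm_percent"].astype(float)
    return df[required]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline thresholds.

    Defaults follow the study workflow this package implements: reads are
    kept at mean Phred >= 30 and length >= 100 bp, OTUs are formed at 98%
    identity and taxa accepted at identity > 98%, query coverage > 98%
    and e-value < 1e-50.
    """

    min_qual: float = 30.0
    min_len: int = 100
    otu_identity: float = 0.98
    min_assign_identity: float = 0.98
    min_assign_coverage: float = 0.98
    max_evalue: float = 1.0e-50
    merge_min_overlap: int = 16
    merge_max_mismatch_frac: float = 0.05
    qual_mode: str = "mean"  # mean | min | ee
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("otu_identity", "min_assign_identity",
                     "min_assign_coverage", "merge_max_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v}: fractions must be in (0, 1]")
        for name in ("min_qual", "min_len", "max_evalue", "merge_min_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qual_mode not in ("mean", "min", "ee"):
            raise ValueError(f"qual_mode={self.qual_mode!r}: use mean|min|ee")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key=value`` file overriding the defaults; '#' comments."""
        values: dict[str, object] = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: expected key=value")
                key, _, val = (s.strip() for s in line.partition("="))
                if key not in valid:
                    raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "qual_mode":
                    values[key] = val
                elif key in ("min_len", "merge_min_overlap", "seed"):
                    values[key] = int(val)
                else:
                    values[key] = float(val)
        return cls(**values)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# tables


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).apply(
        lambda col: col.str.strip() if col.dtype == object else col
    )


def format_percent(x: float) -> str:
    """Render a percentage with exactly two decimals, half away from zero."""
    return str(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
        )
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    percent_cols: Sequence[str] = (),
) -> None:
    """Write a TSV with deterministic column order (as given) and the
    two-decimal percentage dialect for the named columns."""
    out = df.copy()
    for col in percent_cols:
        out[col] = out[col].map(format_percent)
    out.to_csv(path, sep="\t", index=False)


def log_stage(stage: str, **counts: int) -> None:
    """Structured stage log line: stage name plus record counts."""
    parts = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s: %s", stage, parts)
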
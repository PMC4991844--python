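"""Diet-composition tables and the metabarcoding/microhistology
comparison.

Fs is the percentage of a bird group's *assigned* reads attributed to a
food taxon (unassigned OTUs are excluded from the denominator and
reported separately).  Fm, the percentage of identifiable epidermis
fragments from microhistology, is consumed as given.  When a genus-level
assignment coexists with species-level assignments of the same genus the
genus row is labelled "X spp. (except ...)" so the residual reads are
not mistaken for the genus total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from anserdiet.io_core import TaxonomyMap, logger

_RANK_ORDER = {"species": 0, "genus": 1, "family": 2}

DIET_COLUMNS = ["group", "taxon", "rank", "label", "n_reads", "fs", "fm",
                "presence_fraction"]


def _genus_of(taxon: str, rank: str, species_index: Mapping) -> str:
    if rank != "species":
        return taxon if rank == "genus" else ""
    if taxon in species_index:
        return species_index[taxon].genus
    return taxon.split()[0]


def _family_of(taxon: str, rank: str, species_index: Mapping,
               genus_family: Mapping[str, str]) -> str:
    if rank == "family":
        return taxon
    if rank == "species" and taxon in species_index:
        return species_index[taxon].family
    if rank == "genus" and taxon in genus_family:
        return genus_family[taxon]
    return ""


def _indexes(taxonomy: TaxonomyMap | None):
    species_index = taxonomy.species_index() if taxonomy else {}
    genus_family = (
        {t.genus: t.family for t in taxonomy.values() if t.genus}
        if taxonomy else {}
    )
    return species_index, genus_family


def table_from_counts(
    counts: pd.DataFrame,
    microhistology: pd.DataFrame | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> pd.DataFrame:
    """Build the diet table from per-(group, taxon, rank) read counts.

    ``counts`` needs columns group, taxon, rank, n_reads.  Fs is
    100 * n_reads / (group's total reads).  Microhistology rows with no
    read counterpart are appended with zero reads so both methods share
    one table.  Rows are ordered per group by Fs descending then taxon.
    """
    df = counts.copy()
    df["n_reads"] = df["n_reads"].astype(int)
    if microhistology is not None:
        fm = microhistology.rename(columns={"fm_percent": "fm"})
        df = df.merge(fm, on=["group", "taxon", "rank"], how="outer")
        df["n_reads"] = df["n_reads"].fillna(0).astype(int)
        df["fm"] = df["fm"].fillna(0.0)
    else:
        df["fm"] = 0.0
    out_rows = []
    for group, sub in df.groupby("group", sort=True):
        total = sub["n_reads"].sum()
        sub = sub.copy()
        sub["fs"] = 100.0 * sub["n_reads"] / total if total else 0.0
        sub["label"] = [
            _residual_label(row, sub, taxonomy) for _, row in sub.iterrows()
        ]
        sub = sub.sort_values(["fs", "taxon"], ascending=[False, True])
        out_rows.append(sub)
    out = pd.concat(out_rows, ignore_index=True)
    out["presence_fraction"] = out.get("presence_fraction", float("nan"))
    return out[DIET_COLUMNS]


def _residual_label(row, group_df: pd.DataFrame,
                    taxonomy: TaxonomyMap | None) -> str:
    """Table-style label; coarse rows that coexist with finer rows of the
    same lineage get an "(except ...)" clause."""
    species_index, genus_family = _indexes(taxonomy)
    taxon, rank = row["taxon"], row["rank"]
    if rank == "species":
        return taxon
    finer = []
    for _, other in group_df.iterrows():
        if other["taxon"] == taxon and other["rank"] == rank:
            continue
        if _RANK_ORDER.get(other["rank"], 3) >= _RANK_ORDER.get(rank, 3):
            continue
        if rank == "genus":
            member = _genus_of(other["taxon"], other["rank"],
                               species_index) == taxon
        else:
            member = _family_of(other["taxon"], other["rank"],
                                species_index, genus_family) == taxon
        if member and other["n_reads"] > 0:
            finer.append(other["taxon"])
    base = taxon if taxon.endswith((" sp.", " spp.")) else f"{taxon} spp."
    if finer:
        return f"{base} (except {', '.join(sorted(finer))})"
    return base


def diet_table(
    assignments: Sequence,
    otu_counts: pd.DataFrame,
    sample_groups: Mapping[str, str],
    microhistology: pd.DataFrame | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> pd.DataFrame:
    """Aggregate OTU assignments into the per-group diet table.

    ``otu_counts`` is the OTU x sample count table from the pipeline;
    every sample must be mapped to a group.  Reads of unassigned OTUs
    are excluded (and logged).  Adds the per-group fraction of samples
    containing each taxon.
    """
    missing = [s for s in otu_counts.columns if s not in sample_groups]
    if missing:
        raise ValueError(f"samples without group mapping: {missing}")
    assigned = {a.otu_id: a for a in assignments
                if a.rank != "unassigned"}
    rows = []
    for sample in otu_counts.columns:
        group = sample_groups[sample]
        sample_total = 0
        for otu_id, count in otu_counts[sample].items():
            if count == 0 or otu_id not in assigned:
                continue
            a = assigned[otu_id]
            rows.append((group, a.taxon, a.rank, sample, int(count)))
            sample_total += int(count)
        if sample_total == 0:
            logger.warning("diet_table: sample %s has zero assigned reads",
                           sample)
    tidy = pd.DataFrame(
        rows, columns=["group", "taxon", "rank", "sample", "n_reads"]
    )
    if tidy.empty:
        return pd.DataFrame(columns=DIET_COLUMNS)
    counts = (
        tidy.groupby(["group", "taxon", "rank"], as_index=False)["n_reads"]
        .sum()
    )
    table = table_from_counts(counts, microhistology, taxonomy)
    # per-group presence fractions
    n_samples = {
        g: sum(1 for s in otu_counts.columns if sample_groups[s] == g)
        for g in set(sample_groups.values())
    }
    pres = (
        tidy.groupby(["group", "taxon", "rank"])["sample"]
        .nunique()
        .reset_index(name="n_present")
    )
    table = table.drop(columns=["presence_fraction"]).merge(
        pres, on=["group", "taxon", "rank"], how="left"
    )
    table["presence_fraction"] = [
        (row["n_present"] / n_samples[row["group"]])
        if pd.notna(row["n_present"]) else 0.0
        for _, row in table.iterrows()
    ]
    return table[DIET_COLUMNS]


def presence_table(
    assignments: Sequence,
    otu_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample taxon incidence: present iff >= 1 read of an OTU
    assigned to the taxon; taxa with zero reads overall are absent."""
    assigned = {a.otu_id: a for a in assignments if a.rank != "unassigned"}
    taxa: dict[tuple[str, str], dict[str, int]] = {}
    for otu_id, a in assigned.items():
        if otu_id not in otu_counts.index:
            continue
        key = (a.taxon, a.rank)
        row = taxa.setdefault(key, {s: 0 for s in otu_counts.columns})
        for sample in otu_counts.columns:
            row[sample] += int(otu_counts.loc[otu_id, sample])
    records = []
    for (taxon, rank), per_sample in sorted(taxa.items()):
        if sum(per_sample.values()) == 0:
            continue
        rec = {"taxon": taxon, "rank": rank}
        present = {s: int(c > 0) for s, c in per_sample.items()}
        rec.update(present)
        rec["fraction"] = sum(present.values()) / len(present)
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class MethodComparison:
    """Rank-aware detection overlap between the two methods."""

    group: str
    shared: set[str] = field(default_factory=set)
    metabarcoding_only: set[str] = field(default_factory=set)
    microhistology_only: set[str] = field(default_factory=set)
    rank_detail: pd.DataFrame | None = None
    unmapped_taxa: set[str] = field(default_factory=set)


def _detections(df: pd.DataFrame, value_col: str) -> set[tuple[str, str]]:
    sub = df[df[value_col] > 0]
    return {(str(r["taxon"]), str(r["rank"])) for _, r in sub.iterrows()}


def _rank_match(
    meta: set[tuple[str, str]],
    micro: set[tuple[str, str]],
    taxonomy: TaxonomyMap | None,
) -> tuple[set, set, set, list, set]:
    """Consumed matching: exact (taxon, rank) pairs first, then coarse
    records pair with leftover finer records of their lineage."""
    species_index, genus_family = _indexes(taxonomy)
    unmapped: set[str] = set()

    def genus(t, r):
        g = _genus_of(t, r, species_index)
        if r == "species" and t not in species_index:
            unmapped.add(t)
        return g

    def family(t, r):
        return _family_of(t, r, species_index, genus_family)

    shared_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = []
    meta_left = set(meta)
    micro_left = set(micro)
    for d in meta & micro:
        shared_pairs.append((d, d))
        meta_left.discard(d)
        micro_left.discard(d)
    # genus-level record on one side vs congeneric species on the other
    for side_a, side_b in ((meta_left, micro_left), (micro_left, meta_left)):
        for t, r in sorted(side_a):
            if r != "genus":
                continue
            partners = [
                (t2, r2) for t2, r2 in sorted(side_b)
                if r2 == "species" and genus(t2, r2) == t
            ]
            if partners:
                side_a.discard((t, r))
                for p in partners:
                    side_b.discard(p)
                    if side_a is meta_left:
                        shared_pairs.append(((t, r), p))
                    else:
                        shared_pairs.append((p, (t, r)))
    # family-level record vs leftover members of the family
    for side_a, side_b in ((meta_left, micro_left), (micro_left, meta_left)):
        for t, r in sorted(side_a):
            if r != "family":
                continue
            partners = [
                (t2, r2) for t2, r2 in sorted(side_b)
                if family(t2, r2) == t
            ]
            if partners:
                side_a.discard((t, r))
                for p in partners:
                    side_b.discard(p)
                    if side_a is meta_left:
                        shared_pairs.append(((t, r), p))
                    else:
                        shared_pairs.append((p, (t, r)))
    shared = {m[0] for m, _ in shared_pairs} | {m[0] for _, m in shared_pairs}
    return meta_left, micro_left, shared, shared_pairs, unmapped


def compare_methods(
    diet: pd.DataFrame,
    microhistology: pd.DataFrame,
    taxonomy: TaxonomyMap | None = None,
    pooled: bool = True,
) -> dict[str, MethodComparison]:
    """Classify detected taxa as shared / metabarcoding-only /
    microhistology-only, per group and (with ``pooled``) for the union
    of groups.

    Matching is rank-aware: after exact (taxon, rank) matches are
    consumed, an unmatched genus-level record matches the other method's
    unmatched congeneric species-level records, and an unmatched
    family-level record matches unmatched members of that family.
    Species names absent from the reference taxonomy fall back to
    binomial-prefix genus matching and are flagged in
    ``unmapped_taxa``.  Swapping the two inputs swaps the "only" sets
    exactly.
    """
    fm = microhistology.rename(columns={"fm_percent": "fm"})
    out: dict[str, MethodComparison] = {}
    groups = sorted(set(diet["group"]) | set(fm["group"]))
    scopes: list[tuple[str, pd.DataFrame, pd.DataFrame]] = [
        (g, diet[diet["group"] == g], fm[fm["group"] == g]) for g in groups
    ]
    if pooled:
        scopes.append(("all", diet, fm))
    for name, d_sub, m_sub in scopes:
        meta = _detections(d_sub, "n_reads")
        micro = _detections(m_sub, "fm")
        meta_left, micro_left, _, pairs, unmapped = _rank_match(
            meta, micro, taxonomy
        )
        detail = pd.DataFrame(
            [
                {
                    "metabarcoding_taxon": a[0],
                    "metabarcoding_rank": a[1],
                    "microhistology_taxon": b[0],
                    "microhistology_rank": b[1],
                    "finer_method": (
                        "equal" if _RANK_ORDER.get(a[1], 3) ==
                        _RANK_ORDER.get(b[1], 3)
                        else "metabarcoding"
                        if _RANK_ORDER.get(a[1], 3) < _RANK_ORDER.get(b[1], 3)
                        else "microhistology"
                    ),
                }
                for a, b in sorted(pairs)
            ]
        )
        out[name] = MethodComparison(
            group=name,
            shared={a[0] for a, _ in pairs} | {b[0] for _, b in pairs},
            metabarcoding_only={t for t, _ in meta_left},
            microhistology_only={t for t, _ in micro_left},
            rank_detail=detail,
            unmapped_taxa=unmapped,
        )
    return out
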
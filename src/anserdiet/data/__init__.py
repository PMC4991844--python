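"""Packaged study tables.

Small tab-separated fixtures derived from the published study tables:
the reference-library taxonomy of the 70 sampled plant species, the
per-taxon assigned read counts of the two goose groups, and the
microhistology percentages for the same samples.  These are *inputs*
(the sequencing deposit itself is not shipped); all percentages and
comparisons are recomputed from them by the package.
"""

from importlib.resources import files

import pandas as pd

from anserdiet.io_core import TaxonomyMap, read_microhistology, read_table


def _path(name: str):
    return files("anserdiet.data").joinpath(name)


def load_study_taxonomy() -> TaxonomyMap:
    """Taxonomy of the 70 reference-library plant species."""
    return TaxonomyMap.read(str(_path("shengjin_taxonomy.tsv")))


def load_read_counts() -> pd.DataFrame:
    """Assigned trnL read counts per (group, taxon, rank)."""
    df = read_table(str(_path("goose_diet_reads.tsv")))
    df["n_reads"] = df["n_reads"].astype(int)
    return df


def load_microhistology() -> pd.DataFrame:
    """Microhistology Fm percentages per (group, taxon, rank)."""
    return read_microhistology(str(_path("goose_microhistology.tsv")))
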
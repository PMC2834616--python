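"""Bundled reference fixtures.

Three small tables ship with the package: the 29 schizophrenia-associated
miRNA precursors with coordinates and conservation classes, the 32
TF-miRNA-gene feed-forward loops found among them, and the FFL counts for
the three miRNA sets (disease, brain-expressed, non-brain) across four
candidate-gene lists together with the published p-values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .io import read_mirna_annotation
from .types import MiRNARecord


@dataclass(frozen=True)
class FFLRow:
    """One row of the reference FFL table (matrices already merged)."""

    no: int
    gene: str
    mirna: str
    matrix_ids: tuple[str, ...]
    consensus: str
    tf_symbols: tuple[str, ...]


@dataclass(frozen=True)
class FixtureBundle:
    mirnas: tuple[MiRNARecord, ...]
    ffl_table: tuple[FFLRow, ...]
    counts_table: pd.DataFrame


def _data_path(name: str):
    return importlib.resources.files("mirtfnet.data") / name


def load_paper_fixtures() -> FixtureBundle:
    """Load the bundled miRNA annotation, FFL table and set-count table."""
    with importlib.resources.as_file(_data_path("sz_mirnas.gff3")) as p:
        mirnas = tuple(read_mirna_annotation(p))

    with importlib.resources.as_file(_data_path("sz_ffls.tsv")) as p:
        ffl_df = pd.read_csv(p, sep="\t", dtype=str)
    rows = tuple(
        FFLRow(
            no=int(r.no),
            gene=r.gene,
            mirna=r.mirna,
            matrix_ids=tuple(r.matrices.split(",")),
            consensus=r.consensus,
            tf_symbols=tuple(r.tf_symbols.split(",")),
        )
        for r in ffl_df.itertuples()
    )

    with importlib.resources.as_file(_data_path("ffl_set_counts.tsv")) as p:
        counts = pd.read_csv(p, sep="\t")
    return FixtureBundle(mirnas, rows, counts)


def matrix_tf_map_from_fixture(
    rows=None,
) -> dict[str, tuple[str, ...]]:
    """Matrix -> TF-symbol sidecar derived from the FFL table."""
    if rows is None:
        rows = load_paper_fixtures().ffl_table
    out: dict[str, tuple[str, ...]] = {}
    for row in rows:
        for m in row.matrix_ids:
            out.setdefault(m, row.tf_symbols)
    return out
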
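"""Readers and writers for the plain-text interchange formats used by the
pipeline: GMT gene sets, expression TSV, design CSV, regulon/ortholog
tables, bioactivity tables and JSON run logs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


# -- GMT gene sets -----------------------------------------------------


def gmt_dumps(sets: Mapping[str, list[str] | set[str]]) -> str:
    """Serialise a gene-set collection to GMT text.

    Each line: ``set_id<TAB>description<TAB>member...``.  Members are
    written in sorted order so identical collections serialise to
    identical bytes.
    """
    lines = []
    for set_id in sets:
        members = sorted(sets[set_id])
        lines.append("\t".join([set_id, "na", *members]))
    return "\n".join(lines) + "\n"


def write_gmt(sets: Mapping[str, list[str] | set[str]], path: str | Path) -> None:
    Path(path).write_text(gmt_dumps(sets))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        parts = line.split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets


# -- tabular formats ---------------------------------------------------


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Expression TSV: gene rows, sample columns."""
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- run log -----------------------------------------------------------


def write_run_log(entries: dict, path: str | Path) -> None:
    """JSON run log capturing seeds, thresholds and warnings."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))


def read_run_log(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
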
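"""Packaged study fixtures: the printed profile matrix and isolate metadata.

The profile table covers the 42 isolates whose allelic profiles are
printed in the source study (24 distinct STs).  Three further isolates
(qz543, qz568, qz772) and one ST label (ST11) appear in the study's
counts but not in its printed profile matrix; they are deliberately NOT
imputed here — analyses in this package target what the printed data
support.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .scheme import IsolateRecord, read_profile_table

__all__ = ["FIXTURES", "load_fixture", "fixture_records"]

FIXTURES = ("table4_profiles", "table1_metadata", "table2_references")


def _path(name: str) -> Path:
    return Path(str(importlib.resources.files("mlstpop").joinpath("data", f"{name}.tsv")))


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table4_profiles`` returns a list of :class:`IsolateRecord`;
    the metadata fixtures return :class:`pandas.DataFrame`.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    if name == "table4_profiles":
        return read_profile_table(_path(name))
    return pd.read_csv(_path(name), sep="\t")


def fixture_records() -> list[IsolateRecord]:
    """Profile fixture with sampling metadata merged in.

    Reference strains (absent from the field-isolate metadata) get
    source_type ``standard``.
    """
    records = load_fixture("table4_profiles")
    meta = load_fixture("table1_metadata").set_index("isolate")
    for rec in records:
        if rec.isolate_id in meta.index:
            row = meta.loc[rec.isolate_id]
            rec.source_type = str(row["source"])
            rec.region = str(row["region"])
            rec.year = int(row["year"])
        else:
            rec.source_type = "standard"
    return records
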
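"""Reading and writing of the package's delimited-text formats.

All formats are plain UTF-8 TSV with a mandatory header; missing values are
empty fields.  Writers are canonical so that write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model_core import InvalidArgumentError, ItemBank

ENCOUNTER_COLUMNS = ("person_id", "item_id", "y", "rt_seconds",
                     "ac_count", "tr_count", "iv_count")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(float(value))
    return str(value)


def write_encounters(table: pd.DataFrame, path) -> None:
    cols = [c for c in ENCOUNTER_COLUMNS if c in table.columns]
    missing = [c for c in ("person_id", "item_id", "y") if c not in cols]
    if missing:
        raise InvalidArgumentError(f"encounter table missing {missing}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in table[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ("person_id", "item_id", "y") if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"encounter table missing {missing}")
    return df


def write_item_bank(bank: ItemBank, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("item_id\tn_options\n")
        for iid, m in zip(bank.item_ids, bank.n_options):
            fh.write(f"{iid}\t{m}\n")


def read_item_bank(path) -> ItemBank:
    df = pd.read_csv(path, sep="\t")
    if "item_id" not in df.columns or "n_options" not in df.columns:
        raise InvalidArgumentError("item bank needs item_id and n_options")
    return ItemBank.from_frame(df)


def write_table(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="",
              float_format=float_format, lineterminator="\n")
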
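"""Reading PTB-XL-style corpora: waveforms, metadata tables, label mapping.

A corpus is a directory of WFDB record pairs plus two CSV tables following
PTB-XL's conventions:

* a per-record table (``ptbxl_database.csv`` dialect): record id, ``age``,
  ``sex`` (0 = male, 1 = female), ``scp_codes`` (a serialized code ->
  likelihood dict), ``strat_fold``, and the waveform paths ``filename_lr``
  (100 Hz) / ``filename_hr`` (500 Hz);
* an SCP statement table (``scp_statements.csv`` dialect): one row per code
  with ``diagnostic`` flag and ``diagnostic_class`` / ``diagnostic_subclass``
  columns mapping each diagnostic code into the superclass/subclass taxonomy.
"""

from __future__ import annotations

import ast
import logging
import os
from typing import Literal

import pandas as pd

from .records import ECGRecord, DiagnosticLabel, assign_split
from .taxonomy import SUBCLASSES, SUPERCLASSES, canonical_subclass
from .wfdb_io import WFDBFormatError, read_wfdb

logger = logging.getLogger(__name__)

#: Sentinel results of label mapping for records without a usable single label.
UNLABELED: Literal["unlabeled"] = "unlabeled"
AMBIGUOUS: Literal["ambiguous"] = "ambiguous"


def read_record(path: str, fs: int = 100) -> ECGRecord:
    """Read one 12-lead waveform (metadata is merged separately).

    ``path`` is the WFDB record path without extension; ``fs`` the expected
    sampling rate (100 or 500 Hz). Raises ``WFDBFormatError`` if the record
    does not have exactly 12 channels or 10 s of samples.
    """
    signal, file_fs, _names = read_wfdb(path)
    if int(file_fs) != int(fs):
        raise WFDBFormatError(
            f"{path}: header sampling rate {file_fs} != requested {fs}"
        )
    if signal.shape[1] != 12:
        raise WFDBFormatError(
            f"{path}: expected 12 channels, found {signal.shape[1]}"
        )
    if signal.shape[0] != 10 * int(fs):
        raise WFDBFormatError(
            f"{path}: expected {10 * int(fs)} samples, found {signal.shape[0]}"
        )
    return ECGRecord(
        record_id=os.path.basename(path), signal=signal, fs=int(fs)
    )


def _parse_scp_codes(raw: object) -> dict[str, float] | None:
    if isinstance(raw, dict):
        return {str(k): float(v) for k, v in raw.items()}
    try:
        parsed = ast.literal_eval(str(raw))
        if not isinstance(parsed, dict):
            return None
        return {str(k): float(v) for k, v in parsed.items()}
    except (ValueError, SyntaxError, TypeError):
        return None


def load_metadata(records_csv: str, scp_csv: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the two metadata tables.

    Returns ``(records, taxonomy)``. ``records`` has one row per record with
    parsed ``scp_codes`` dicts; rows whose ``scp_codes`` cannot be parsed are
    dropped and counted in the log. ``taxonomy`` is indexed by SCP code with
    ``superclass`` / ``subclass`` columns for diagnostic statements.
    """
    records = pd.read_csv(records_csv, index_col=0)
    required = {"scp_codes", "age", "sex", "strat_fold"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"{records_csv} lacks required columns: {sorted(missing)}")

    scp = pd.read_csv(scp_csv, index_col=0)
    if "diagnostic_class" not in scp.columns:
        raise ValueError(f"{scp_csv} lacks the diagnostic_class column")

    parsed = records["scp_codes"].map(_parse_scp_codes)
    bad = parsed.isna()
    if bad.any():
        logger.warning(
            "dropped %d record(s) with unparseable scp_codes", int(bad.sum())
        )
    records = records.loc[~bad].copy()
    records["scp_codes"] = parsed.loc[~bad]

    taxonomy = scp.copy()
    if "diagnostic" in taxonomy.columns:
        taxonomy = taxonomy[taxonomy["diagnostic"] == 1]
    taxonomy = taxonomy.rename(columns={"diagnostic_class": "superclass"})
    if "diagnostic_subclass" in taxonomy.columns:
        taxonomy = taxonomy.rename(columns={"diagnostic_subclass": "subclass"})
    else:
        taxonomy["subclass"] = taxonomy.index
    return records, taxonomy[["superclass", "subclass"]]


def map_scp_to_label(
    scp_codes: dict[str, float],
    taxonomy: pd.DataFrame,
    min_likelihood: float = 100.0,
) -> DiagnosticLabel | Literal["unlabeled", "ambiguous"]:
    """Resolve a record's SCP codes to a single diagnosis.

    Codes at or above ``min_likelihood`` are mapped through the taxonomy
    table. Exactly one superclass -> that label (with its subclass when
    unique); no diagnostic codes -> ``"unlabeled"``; several superclasses ->
    ``"ambiguous"`` (single-label tasks exclude such records). Codes absent
    from the taxonomy — form/rhythm statements, for example — are logged and
    ignored.
    """
    supers: set[str] = set()
    subs: set[str] = set()
    for code, likelihood in scp_codes.items():
        if likelihood < min_likelihood:
            continue
        code = canonical_subclass(code)
        if code not in taxonomy.index:
            logger.debug("ignoring non-diagnostic SCP code %s", code)
            continue
        sup = taxonomy.loc[code, "superclass"]
        if not isinstance(sup, str) or sup not in SUPERCLASSES:
            continue
        supers.add(sup)
        sub = canonical_subclass(str(taxonomy.loc[code, "subclass"]))
        if sub in SUBCLASSES:
            subs.add(sub)
    if not supers:
        return UNLABELED
    if len(supers) > 1:
        return AMBIGUOUS
    superclass = supers.pop()
    matching = {s for s in subs if SUBCLASSES[s][0] == superclass}
    subclass = matching.pop() if len(matching) == 1 else None
    return DiagnosticLabel(superclass=superclass, subclass=subclass)


def load_corpus(
    corpus_dir: str,
    fs: int = 100,
    records_csv: str | None = None,
    scp_csv: str | None = None,
    min_likelihood: float = 100.0,
) -> list[tuple[ECGRecord, DiagnosticLabel | str]]:
    """Load every record of a corpus directory with its resolved label.

    Returns ``(record, label)`` pairs where ``label`` is a
    :class:`DiagnosticLabel` or one of the sentinels ``"unlabeled"`` /
    ``"ambiguous"``. Demographics and folds from the metadata table are
    merged onto each :class:`ECGRecord`.
    """
    records_csv = records_csv or os.path.join(corpus_dir, "ptbxl_database.csv")
    scp_csv = scp_csv or os.path.join(corpus_dir, "scp_statements.csv")
    meta, taxonomy = load_metadata(records_csv, scp_csv)
    path_col = "filename_lr" if fs == 100 else "filename_hr"
    out: list[tuple[ECGRecord, DiagnosticLabel | str]] = []
    for rec_id, row in meta.iterrows():
        rel = row.get(path_col)
        if not isinstance(rel, str):
            logger.warning("record %s has no %s path; skipped", rec_id, path_col)
            continue
        rec = read_record(os.path.join(corpus_dir, rel), fs=fs)
        rec.record_id = str(rec_id)
        age = row.get("age")
        rec.age = float(age) if pd.notna(age) else None
        sex = row.get("sex")
        if pd.notna(sex):
            rec.sex = "female" if int(sex) == 1 else "male"
        rec.scp_codes = dict(row["scp_codes"])
        rec.fold = int(row["strat_fold"])
        out.append((rec, map_scp_to_label(rec.scp_codes, taxonomy, min_likelihood)))
    return out


def partition_of(record: ECGRecord) -> str:
    """Partition (train/validation/test) implied by a record's fold."""
    if record.fold is None:
        raise ValueError(f"record {record.record_id} has no fold")
    return assign_split(record.fold)
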
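"""CSV readers/writers with schema validation and manifest-hash headers.

One CSV dialect only: comma-separated, "." decimal, mandatory header
row, UTF-8.  Lines starting with '#' are manifest/header comments and
are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

RATING_COLUMNS = ["listener_id", "speaker_id", "condition", "scale", "rating"]
ITEM_COLUMNS = ["speaker_id", "instrument", "item", "response"]
SPEAKER_COLUMNS = ["speaker_id", "age", "sex"]


class SchemaError(ValueError):
    """The input violates the documented CSV schema (itemized message)."""


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_csv(df: pd.DataFrame, path, manifest_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if manifest_hash:
            fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, index=False)
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config snapshot."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_ratings(
    path, likert_min: int = 1, likert_max: int = 7
) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV.

    Condition and scale labels are casefolded and stripped (so
    "Likeable" normalizes to "likeable").  Out-of-range or non-integer
    ratings and duplicate (listener, speaker, condition, scale) keys are
    rejected with row numbers (1-based data rows, header excluded).
    """
    df = read_csv(path)
    _require_columns(df, RATING_COLUMNS, f"ratings file {path}")
    df = df.copy()
    for col in ("condition", "scale"):
        df[col] = df[col].astype(str).str.strip().str.casefold()

    problems: list[str] = []
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad = ratings.isna() | (ratings != ratings.round()) | (ratings < likert_min) | (
        ratings > likert_max
    )
    for pos in df.index[bad][:20]:
        problems.append(
            f"row {pos + 1}: rating {df.loc[pos, 'rating']!r} not an integer in "
            f"[{likert_min}, {likert_max}]"
        )
    key = ["listener_id", "speaker_id", "condition", "scale"]
    dup = df.duplicated(subset=key, keep="first")
    for pos in df.index[dup][:20]:
        problems.append(f"row {pos + 1}: duplicate key {tuple(df.loc[pos, key])}")
    if problems:
        raise SchemaError("ratings validation failed: " + "; ".join(problems))
    df["rating"] = ratings.astype(int)
    return df


def read_items(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, ITEM_COLUMNS, f"items file {path}")
    return df


def read_speakers(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, SPEAKER_COLUMNS, f"speaker file {path}")
    return df
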
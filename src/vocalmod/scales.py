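"""Sum scoring of the QCAE and SD3 self-report instruments.

Item-to-subscale assignment and reverse keying are read from editable
YAML keymaps shipped with the package (``vocalmod/data``).  Scoring is a
plain subscale sum with hard validation: missing items, out-of-range
responses and wrong item counts raise itemized errors; there is no
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml


class ScoringValidationError(ValueError):
    """Item responses violate the instrument contract (itemized message)."""


class UndefinedAlphaError(ValueError):
    """Cronbach's alpha is undefined (zero total-score variance)."""


@dataclass(frozen=True)
class Keymap:
    instrument: str
    response_min: int
    response_max: int
    subscales: Mapping[str, tuple[int, ...]]
    reverse_keyed: tuple[int, ...] = field(default_factory=tuple)

    @property
    def items(self) -> tuple[int, ...]:
        out: list[int] = []
        for ids in self.subscales.values():
            out.extend(ids)
        return tuple(sorted(out))

    @property
    def n_items(self) -> int:
        return len(self.items)


def load_keymap(source) -> Keymap:
    """Load a keymap from a YAML path, or from the packaged defaults.

    ``source`` may be a filesystem path or one of the instrument names
    "QCAE" / "SD3" (case-insensitive) to get the shipped default.
    """
    if isinstance(source, str) and source.upper() in ("QCAE", "SD3"):
        ref = resources.files("vocalmod.data") / f"{source.lower()}_keymap.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    subscales = {k: tuple(int(i) for i in v) for k, v in raw["subscales"].items()}
    all_items = [i for ids in subscales.values() for i in ids]
    if len(all_items) != len(set(all_items)):
        raise ScoringValidationError("keymap assigns an item to more than one subscale")
    return Keymap(
        instrument=str(raw["instrument"]),
        response_min=int(raw["response_min"]),
        response_max=int(raw["response_max"]),
        subscales=subscales,
        reverse_keyed=tuple(int(i) for i in raw.get("reverse_keyed", []) or ()),
    )


def _as_response_dict(responses) -> dict[int, int]:
    if isinstance(responses, pd.Series):
        return {int(k): v for k, v in responses.items()}
    return {int(k): v for k, v in dict(responses).items()}


def validate_responses(responses, keymap: Keymap) -> dict[int, int]:
    """Check completeness and ranges; return the validated item->response map."""
    resp = _as_response_dict(responses)
    problems: list[str] = []
    expected = set(keymap.items)
    got = set(resp)
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing:
        problems.append(f"missing items: {missing}")
    if extra:
        problems.append(f"unexpected items: {extra}")
    if len(resp) != keymap.n_items:
        problems.append(f"expected {keymap.n_items} items, got {len(resp)}")
    for item in sorted(expected & got):
        v = resp[item]
        if not float(v).is_integer() or not (
            keymap.response_min <= int(v) <= keymap.response_max
        ):
            problems.append(
                f"item {item}: response {v!r} outside "
                f"[{keymap.response_min}, {keymap.response_max}]"
            )
    if problems:
        raise ScoringValidationError(
            f"{keymap.instrument} validation failed: " + "; ".join(problems)
        )
    return {k: int(v) for k, v in resp.items()}


def apply_reverse_keying(responses, keymap: Keymap) -> dict[int, int]:
    """Reverse-keyed items are mapped r -> min + max - r; others unchanged.

    Applying this twice is the identity.
    """
    resp = _as_response_dict(responses)
    flip = keymap.response_min + keymap.response_max
    return {
        item: (flip - int(v) if item in keymap.reverse_keyed else int(v))
        for item, v in resp.items()
    }


def _score(responses, keymap: Keymap) -> dict[str, int]:
    resp = validate_responses(responses, keymap)
    resp = apply_reverse_keying(resp, keymap)
    return {name: sum(resp[i] for i in ids) for name, ids in keymap.subscales.items()}


def score_qcae(responses, keymap: Keymap | None = None) -> tuple[int, int]:
    """Score a 31-item QCAE response set.

    Returns (cognitive_empathy, affective_empathy) sum scores, which by
    construction lie in 19-76 and 12-48 respectively.
    """
    keymap = keymap or load_keymap("QCAE")
    scores = _score(responses, keymap)
    return scores["cognitive_empathy"], scores["affective_empathy"]


def score_sd3(responses, keymap: Keymap | None = None) -> tuple[int, int]:
    """Score a 27-item SD3 response set.

    Returns (machiavellianism, psychopathy) sum scores (each 9-45).
    Narcissism items are validated but not returned.
    """
    keymap = keymap or load_keymap("SD3")
    scores = _score(responses, keymap)
    return scores["machiavellianism"], scores["psychopathy"]


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for an n-respondents x k-items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with sample (ddof=1) variances.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be 2-D with at least 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise UndefinedAlphaError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def score_profiles(
    items: pd.DataFrame,
    speakers: pd.DataFrame,
    qcae_keymap: Keymap | None = None,
    sd3_keymap: Keymap | None = None,
) -> pd.DataFrame:
    """Score long-format item responses into per-speaker reactivity profiles.

    ``items`` columns: speaker_id, instrument, item, response.
    ``speakers`` columns: speaker_id, age, sex.

    Returns one row per speaker with the four index sum scores plus age
    and sex.
    """
    qcae_keymap = qcae_keymap or load_keymap("QCAE")
    sd3_keymap = sd3_keymap or load_keymap("SD3")
    rows = []
    for speaker_id, grp in items.groupby("speaker_id", sort=True):
        qcae = grp[grp["instrument"].str.upper() == "QCAE"].set_index("item")["response"]
        sd3 = grp[grp["instrument"].str.upper() == "SD3"].set_index("item")["response"]
        cog, aff = score_qcae(qcae, qcae_keymap)
        mach, psych = score_sd3(sd3, sd3_keymap)
        rows.append(
            {
                "speaker_id": speaker_id,
                "cognitive_empathy": cog,
                "affective_empathy": aff,
                "machiavellianism": mach,
                "psychopathy": psych,
            }
        )
    profiles = pd.DataFrame(rows)
    merged = profiles.merge(speakers[["speaker_id", "age", "sex"]], on="speaker_id")
    if len(merged) != len(profiles):
        missing = set(profiles["speaker_id"]) - set(speakers["speaker_id"])
        raise ScoringValidationError(f"speaker table missing ids: {sorted(missing)}")
    return merged
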
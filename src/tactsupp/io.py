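"""Trial-table and trace IO, plus the serializable run configuration.

All tables are UTF-8, comma-separated delimited text with a header row;
times are in ms, amplitudes in mm, EMG in a.u.  External layouts are
adapted through an explicit column-mapping dictionary rather than guessed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

REQUIRED_COLUMNS = [
    "participant_id",
    "session_cue",
    "movement",
    "stimulus_present",
    "amplitude_mm",
    "stim_time_rel_go",
    "movement_onset_rel_go",
    "movement_offset_rel_go",
    "stim_time_rel_onset",
    "response",
]
OPTIONAL_DEFAULTS = {
    "trial_id": None,  # filled with a running index
    "block": 0,
    "valid": True,
    "exclusion_reason": "",
}
VALID_MOVEMENTS = {"baseline", "active", "passive"}
VALID_RESPONSES = {"yes", "no", "missing"}


def read_trial_table(path: str | Path, mapping: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial table.

    ``mapping`` renames external column names to the canonical schema
    (``{"external_name": "canonical_name"}``).  Missing responses become
    the explicit ``missing`` marker; they are never dropped here.  Raises
    :class:`SchemaError` naming the missing column or the malformed row.
    """
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table {path} is missing column(s): {', '.join(missing)}")
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = np.arange(len(df)) if col == "trial_id" else default

    df["response"] = df["response"].where(df["response"].notna(), "missing").astype(str)
    bad = ~df["response"].isin(VALID_RESPONSES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(
            f"malformed response {df['response'].iloc[row]!r} at data row {row + 1}"
        )
    bad = ~df["movement"].isin(VALID_MOVEMENTS)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(
            f"malformed movement {df['movement'].iloc[row]!r} at data row {row + 1}"
        )
    if df["stimulus_present"].dtype == object:
        df["stimulus_present"] = df["stimulus_present"].map(
            {"True": True, "False": False, "1": True, "0": False, True: True, False: False}
        )
    df["stimulus_present"] = df["stimulus_present"].astype(bool)
    df["valid"] = df["valid"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    for col in (
        "amplitude_mm",
        "stim_time_rel_go",
        "movement_onset_rel_go",
        "movement_offset_rel_go",
        "stim_time_rel_onset",
    ):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("trial_id", "t_ms", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} is missing column(s): {', '.join(missing)}")
    return df


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run.

    A run re-executed from its saved config and seed is bit-identical in
    all tabular outputs.
    """

    seed: int = 0
    preset: str = "paper_like"
    n_participants: int = 34
    trial_table: str | None = None
    window_ms: tuple[float, float] = (-300.0, 0.0)
    loglinear: str = "conditional"
    response: str = "d_prime"
    d_eps: float = 0.1
    relc_max: float = 30.0
    bin_sizes: tuple[int, ...] = (2, 2, 3, 2, 2)
    scheduling: str = "adaptive"
    lapse_rate: float = 0.02
    guess_rate: float = 0.02
    outdir: str = "tactsupp_out"
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(self.window_ms)
        d["bin_sizes"] = list(self.bin_sizes)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        d = json.loads(text)
        d["window_ms"] = tuple(d.get("window_ms", (-300.0, 0.0)))
        d["bin_sizes"] = tuple(d.get("bin_sizes", (2, 2, 3, 2, 2)))
        known = {f.name for f in dataclasses.fields(cls)}
        extra = {k: v for k, v in d.items() if k not in known}
        d = {k: v for k, v in d.items() if k in known}
        if extra:
            d.setdefault("extra", {}).update(extra)
        return cls(**d)
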
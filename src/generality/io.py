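"""CSV/TSV readers and writers plus run configuration.

Dialect is fixed: comma-separated (tab for ``.tsv``), UTF-8, "." decimal,
header required.  Missing responses are empty cells in wide format and
absent rows in long format.  Floats are written with 12 significant digits,
enough for lossless round-trips at analysis precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .matrix import DifficultyAssignment, ResponseMatrix, ValidationError
from .population import PopulationSummary, SlodrSplit

__all__ = [
    "read_response_matrix",
    "read_difficulties",
    "read_labelled",
    "write_matrix",
    "write_difficulties",
    "write_metrics",
    "read_metrics",
    "write_summary",
    "RunConfig",
]

FLOAT_FMT = "%.12g"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_response_matrix(path, dialect: str = "auto", domain: str = "unit") -> ResponseMatrix:
    """Read a wide (first column = agent id, header = items) or long CSV/TSV.

    ``dialect="auto"`` treats a file whose header is exactly
    ``agent,item,response`` as long format, anything else as wide.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _sep_for(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need at least an id column and one value column")
    if dialect == "auto":
        dialect = "long" if list(frame.columns[:3]) == ["agent", "item", "response"] else "wide"
    if dialect == "long":
        return ResponseMatrix.from_long(frame, domain=domain)
    if dialect != "wide":
        raise ValidationError(f"unknown dialect {dialect!r}")
    wide = frame.set_index(frame.columns[0])
    wide.index.name = None
    try:
        wide = wide.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric response value ({exc})") from None
    return ResponseMatrix(wide, domain=domain)


def read_difficulties(path, q: float | None = None, origin: float = 0.0,
                      shift: bool = False) -> DifficultyAssignment:
    """Read an ``item,difficulty`` CSV; negative values require shift=True."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in frame.columns}
    if "item" not in cols or "difficulty" not in cols:
        raise ValidationError(f"{path}: expected columns 'item' and 'difficulty'")
    s = frame.set_index(cols["item"])[cols["difficulty"]].astype(float)
    s.index.name = None
    s.name = None
    return DifficultyAssignment.from_series(s, q=q, origin=origin, shift=shift)


def read_labelled(path, label_col: str | None = None):
    """Feature/label CSV for the instance-hardness metrics."""
    from .hardness import LabelledDataset

    frame = pd.read_csv(Path(path), sep=_sep_for(path))
    return LabelledDataset.from_frame(frame, label_col=label_col)


def write_matrix(matrix: ResponseMatrix, path, dialect: str = "wide") -> None:
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        out = matrix.data.copy()
        out.insert(0, "agent", out.index)
        out.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)
    elif dialect == "long":
        matrix.to_long().to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def write_difficulties(difficulties: DifficultyAssignment, path) -> None:
    frame = pd.DataFrame({"item": difficulties.values.index,
                          "difficulty": difficulties.values.to_numpy()})
    frame.to_csv(Path(path), sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def write_metrics(metrics: pd.DataFrame, path) -> None:
    """Per-agent metrics CSV with the documented column set."""
    out = metrics.copy()
    out.insert(0, "agent", out.index)
    out.to_csv(Path(path), sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep=_sep_for(path))
    if "agent" not in frame.columns:
        raise ValidationError(f"{path}: metrics file needs an 'agent' column")
    return frame.set_index("agent")


def _jsonable(value):
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return None if math.isnan(value) else ("inf" if value > 0 else "-inf")
    return value


def write_summary(summary, path) -> None:
    """Population summary (or SLODR split) as JSON; NaN becomes null."""
    if isinstance(summary, PopulationSummary):
        payload = summary.as_dict()
    elif isinstance(summary, SlodrSplit):
        payload = {
            "split_value": summary.split_value,
            "low": summary.low.as_dict(),
            "high": summary.high.as_dict(),
            "slodr_consistent": summary.slodr_consistent,
        }
    elif isinstance(summary, dict):
        payload = summary
    else:
        raise ValidationError(f"cannot serialise {type(summary).__name__}")

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return _jsonable(obj)

    Path(path).write_text(json.dumps(clean(payload), indent=2) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Built by merging a YAML config file with command-line flags (the CLI
    wins on conflict); ``dump`` emits the resolved state for provenance.
    """

    responses: str | None = None
    dialect: str = "auto"
    difficulties: str | None = None
    modality: str | None = None      # set when difficulties come from a transform
    bins: str | int | None = None
    q: float | None = None
    origin: float = 0.0
    interpolation: str = "linear"
    seed: int | None = None
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.difficulties is not None and self.modality is not None:
            raise ValidationError("specify a difficulty file or a modality, not both")
        if self.q is not None and self.q <= 0:
            raise ValidationError("q override must be positive")

    @classmethod
    def from_sources(cls, config_path=None, **cli_flags) -> "RunConfig":
        base: dict = {}
        if config_path:
            loaded = yaml.safe_load(Path(config_path).read_text(encoding="utf-8")) or {}
            if not isinstance(loaded, dict):
                raise ValidationError("config file must contain a mapping")
            base.update(loaded)
        base.update({k: v for k, v in cli_flags.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        extra = {k: base.pop(k) for k in list(base) if k not in known}
        return cls(**base, extra=extra)

    def dump(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)
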
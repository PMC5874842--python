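"""Readers and writers binding the pipeline stages together.

All tabular output is tab-separated UTF-8 text with '.' decimals.
Formatted tables round solubility parameters, differences, chi and Bagley
distances to one decimal (the conventional reporting precision); every
writer has a raw-precision companion so no information is lost.

The package bundles fixture data:

* ``fedors.tsv`` / ``van_krevelen.tsv`` -- group-contribution tables;
* ``compounds/*.yaml`` -- descriptors (group fragmentations, thermal and
  physical properties) for the four model drugs and seven carriers;
* ``printed/table3.tsv`` etc. -- the published parameter/screening tables,
  used as reference inputs for recomputation checks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ObservationRecord, TgEvent
from .errors import ValidationError
from .groups import CompoundDescriptor, GroupContributionTable, load_compound, load_group_table

DRUGS: tuple[str, ...] = ("IBU", "NAP", "CAR", "ITR")
POLYMERS: tuple[str, ...] = ("HP50", "HAS", "PK30", "PVA", "SOL", "EUD", "EUD55")


def data_path(*parts: str) -> Path:
    """Path of a bundled data file."""
    root = resources.files("asdscreen").joinpath("data")
    return Path(str(root.joinpath(*parts)))


def load_bundled_table(method_id: str) -> GroupContributionTable:
    """Bundled Fedors or van Krevelen group-contribution table."""
    return load_group_table(data_path(f"{method_id}.tsv"))


def load_bundled_compound(abbreviation: str) -> CompoundDescriptor:
    """Bundled descriptor by abbreviation (e.g. 'IBU', 'PK30')."""
    return load_compound(data_path("compounds", f"{abbreviation}.yaml"))


def load_all_compounds() -> dict[str, CompoundDescriptor]:
    """All bundled drugs and polymers keyed by abbreviation."""
    return {abbr: load_bundled_compound(abbr) for abbr in DRUGS + POLYMERS}


def load_printed_table(name: str) -> pd.DataFrame:
    """A published reference table bundled as TSV (e.g. 'table3')."""
    return pd.read_csv(data_path("printed", f"{name}.tsv"), sep="\t", comment="#")


def load_printed_rankings() -> pd.DataFrame:
    """Published polymer rankings per predictive method and drug."""
    return pd.read_csv(data_path("printed", "table5.tsv"), sep="\t", comment="#")


# ---------------------------------------------------------------------------
# observation tables


def _format_events(events: Sequence[TgEvent]) -> str:
    return ";".join(f"{e.value:g}:{e.width:g}" for e in events)


def _parse_events(cell: str) -> tuple[TgEvent, ...]:
    cell = cell.strip()
    if not cell or cell == "-":
        return ()
    events = []
    for token in cell.split(";"):
        try:
            value, width = token.split(":")
        except ValueError:
            raise ValidationError(f"malformed Tg event {token!r}; expected value:width")
        events.append(TgEvent(value=float(value), width=float(width)))
    return tuple(events)


_OBS_COLUMNS = [
    "drug", "polymer", "drug_loading", "method", "replicate", "tg_events",
    "melting_detected", "recrystallization_detected", "mesophase_endotherms",
    "xrpd_crystalline",
]


def write_observations(records: Iterable[ObservationRecord], path) -> None:
    """Write an observation table (one row per replicate measurement)."""
    rows = [
        {
            "drug": r.drug,
            "polymer": r.polymer,
            "drug_loading": f"{r.drug_loading:g}",
            "method": r.method,
            "replicate": r.replicate,
            "tg_events": _format_events(r.tg_events),
            "melting_detected": int(r.melting_detected),
            "recrystallization_detected": int(r.recrystallization_detected),
            "mesophase_endotherms": r.mesophase_endotherms,
            "xrpd_crystalline": int(r.xrpd_crystalline),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_observations(path) -> tuple[ObservationRecord, ...]:
    """Read an observation table written by :func:`write_observations`."""
    frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    missing = set(_OBS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"observation table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ObservationRecord(
                drug=str(row.drug),
                polymer=str(row.polymer),
                drug_loading=float(row.drug_loading),
                method=str(row.method),
                replicate=int(row.replicate),
                tg_events=_parse_events(str(row.tg_events)),
                melting_detected=bool(int(row.melting_detected)),
                recrystallization_detected=bool(int(row.recrystallization_detected)),
                mesophase_endotherms=int(row.mesophase_endotherms),
                xrpd_crystalline=bool(int(row.xrpd_crystalline)),
            )
        )
    return tuple(records)


# ---------------------------------------------------------------------------
# generic two-column traces and formatted tables


def write_xy(x, y, path, header: tuple[str, str] = ("x", "y")) -> None:
    """Two-column delimited trace (temperature/heat-flow, 2theta/intensity)."""
    pd.DataFrame({header[0]: x, header[1]: y}).to_csv(path, sep="\t", index=False)


def read_xy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(frame: pd.DataFrame, path, decimals: int | None = 1) -> None:
    """Write a result table; ``decimals`` rounds floats for display
    (None = raw precision)."""
    out = frame.copy()
    if decimals is not None:
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(decimals)
    out.to_csv(path, sep="\t", index=False)


def campaign_truth_frame(truth: Mapping[tuple[str, str, float, str], str]) -> pd.DataFrame:
    """Planted class grid as a tidy frame (drug, polymer, loading, method)."""
    rows = [
        {"drug": d, "polymer": p, "drug_loading": dl, "method": m, "label": lab}
        for (d, p, dl, m), lab in sorted(truth.items())
    ]
    return pd.DataFrame(rows)
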
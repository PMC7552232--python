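"""Reading, validating and writing the interaction and biometric tables.

The canonical in-memory containers are pandas DataFrames:

interactions
    columns ``date`` (datetime64), ``group``, ``winner``, ``loser``,
    ``behavior`` (one of HB, TB, M) and ``seq_index`` — the ordinal position
    of the event in its group's chronology.  Within a date, file order is
    the canonical sequence (the data carry no within-day timestamps, and the
    sequential Elo update is order-sensitive, so the convention must be
    deterministic); this is recorded in the ``attrs`` of the frame.

biometrics
    columns ``date``, ``individual``, ``scl_cm`` (straight carapace length,
    cm) and ``weight_g`` (fasting body mass, g), one row per individual per
    date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

VALID_BEHAVIORS = ("HB", "TB", "M")

INTERACTION_SCHEMA = {
    "date": "date",
    "group": "group",
    "winner": "winner",
    "loser": "loser",
    "behavior": "behavior",
}

BIOMETRIC_SCHEMA = {
    "date": "date",
    "individual": "individual",
    "scl_cm": "scl_cm",
    "weight_g": "weight_g",
}


def _parse_dates(series: pd.Series, dayfirst: bool) -> pd.Series:
    # ISO-8601 by default; day-first parsing only behind the explicit flag,
    # never auto-detected.
    try:
        if dayfirst:
            return pd.to_datetime(series, dayfirst=True, errors="raise")
        return pd.to_datetime(series, format="ISO8601", errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date value: {exc}") from exc


def _require_columns(df: pd.DataFrame, schema: dict, which: str) -> None:
    for canonical, actual in schema.items():
        if actual not in df.columns:
            raise SchemaError(
                f"{which} table is missing required column {actual!r} "
                f"(mapped to {canonical!r})"
            )


def read_interactions(
    path,
    schema: dict | None = None,
    dayfirst: bool = False,
) -> pd.DataFrame:
    """Read a dyadic-interaction CSV and establish the canonical chronology.

    Parameters
    ----------
    path : file path of a CSV with (at least) date, group, winner, loser and
        behavior columns.
    schema : optional map from canonical column names
        (``date, group, winner, loser, behavior``) to the file's column
        names; defaults to the identity map.
    dayfirst : parse dates day-first instead of ISO-8601.

    Returns
    -------
    DataFrame with canonical column names, sorted by date (file order within
    a date) and with a per-group ``seq_index`` column assigned.
    """
    schema = {**INTERACTION_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, float_precision="round_trip")
    _require_columns(raw, schema, "interaction")
    df = pd.DataFrame(
        {canon: raw[actual] for canon, actual in schema.items()}
    )
    if "draw" in raw.columns:
        drawn = raw["draw"].astype(bool)
        if drawn.any():
            raise ValidationError(
                f"draws are not supported; row {int(np.flatnonzero(drawn)[0])} "
                "has draw=True"
            )
    df["date"] = _parse_dates(df["date"], dayfirst)
    df["behavior"] = df["behavior"].astype(str).str.strip().str.upper()
    bad = ~df["behavior"].isin(VALID_BEHAVIORS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}: unknown behavior code {df['behavior'].iloc[row]!r} "
            f"(expected one of {VALID_BEHAVIORS})"
        )
    self_play = df["winner"] == df["loser"]
    if self_play.any():
        row = int(np.flatnonzero(self_play)[0])
        raise ValidationError(
            f"row {row}: winner equals loser ({df['winner'].iloc[row]!r})"
        )
    out = sort_chronology(df)
    out.attrs["same_day_order"] = "file"
    out.attrs["date_dialect"] = "dayfirst" if dayfirst else "iso8601"
    return out


def sort_chronology(df: pd.DataFrame) -> pd.DataFrame:
    """Stable-sort by date (preserving input order within a date) and assign
    ``seq_index`` 0..n−1 within each group."""
    out = df.sort_values("date", kind="stable").reset_index(drop=True)
    out["seq_index"] = out.groupby("group").cumcount()
    return out


def read_biometrics(
    path,
    schema: dict | None = None,
    dayfirst: bool = False,
) -> pd.DataFrame:
    """Read and validate the daily biometric table.

    Enforces strictly positive SCL and weight and at most one record per
    (individual, date); returns per-individual series sorted by date.
    """
    schema = {**BIOMETRIC_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, float_precision="round_trip")
    _require_columns(raw, schema, "biometric")
    df = pd.DataFrame({canon: raw[actual] for canon, actual in schema.items()})
    df["date"] = _parse_dates(df["date"], dayfirst)
    return validate_biometrics(df)


def validate_biometrics(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("scl_cm", "weight_g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~(vals > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: non-positive or missing {col} ({df[col].iloc[row]!r})"
            )
        df[col] = vals.astype(float)
    dup = df.duplicated(subset=["individual", "date"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate record for individual "
            f"{df['individual'].iloc[row]!r} on {df['date'].iloc[row].date()}"
        )
    return df.sort_values(["individual", "date"], kind="stable").reset_index(
        drop=True
    )


def write_interactions(df: pd.DataFrame, path) -> None:
    """Write interactions back to CSV in the canonical dialect (ISO dates)."""
    out = df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    cols = ["date", "group", "winner", "loser", "behavior"]
    if "seq_index" in out.columns:
        cols.append("seq_index")
    out[cols].to_csv(path, index=False)


def write_biometrics(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out[["date", "individual", "scl_cm", "weight_g"]].to_csv(path, index=False)


@dataclass
class DyadSummary:
    """Directed interaction counts and mixture summaries for one group."""

    group_id: object
    n_individuals: int
    n_interactions: int
    directed_counts: dict = field(repr=False)
    individual_totals: dict = field(repr=False)
    behavior_proportions: dict = field(default_factory=dict)
    unobserved_dyad_proportion: float = 0.0

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"group": self.group_id, "winner": w, "loser": l, "count": c}
            for (w, l), c in sorted(self.directed_counts.items(), key=str)
        ]
        return pd.DataFrame(rows, columns=["group", "winner", "loser", "count"])


def summarize_dyads(df: pd.DataFrame, individuals=None) -> DyadSummary:
    """Summarize a single group's interactions as a directed edge list.

    ``individuals`` may widen the roster beyond those observed interacting
    (needed for the unobserved-dyad denominator when some animals never
    interact).
    """
    if len(df) == 0:
        raise ValidationError("cannot summarize an empty record sequence")
    groups = df["group"].unique()
    if len(groups) != 1:
        raise ValidationError(
            f"summarize_dyads expects a single group, got {sorted(map(str, groups))}"
        )
    if individuals is None:
        individuals = sorted(
            set(df["winner"]).union(df["loser"]), key=str
        )
    individuals = list(individuals)
    n = len(individuals)
    directed = (
        df.groupby(["winner", "loser"]).size().to_dict()
    )
    wins = df["winner"].value_counts()
    losses = df["loser"].value_counts()
    totals = {
        ind: int(wins.get(ind, 0)) + int(losses.get(ind, 0)) for ind in individuals
    }
    props = (df["behavior"].value_counts(normalize=True)).to_dict()
    observed_pairs = {frozenset(pair) for pair in directed}
    n_pairs = n * (n - 1) // 2
    unobserved = (
        (n_pairs - len(observed_pairs)) / n_pairs if n_pairs else 0.0
    )
    return DyadSummary(
        group_id=groups[0],
        n_individuals=n,
        n_interactions=int(len(df)),
        directed_counts={k: int(v) for k, v in directed.items()},
        individual_totals=totals,
        behavior_proportions={b: float(p) for b, p in props.items()},
        unobserved_dyad_proportion=float(unobserved),
    )


def iter_groups(df: pd.DataFrame):
    """Yield (group_id, single-group frame) pairs in sorted group order."""
    for gid in sorted(df["group"].unique(), key=str):
        yield gid, df[df["group"] == gid].reset_index(drop=True)
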
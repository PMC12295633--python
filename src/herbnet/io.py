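"""Readers and writers for every tabular format the pipeline touches.

TSV is the canonical dialect (STRING exports and systems-pharmacology
database dumps are tab-separated); CSV is accepted via ``sep=","``.  All
files are UTF-8.  Readers never silently drop rows: every reject is
raised (or, for the edge reader, counted and reported).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .adme import IngredientRecord
from .behavior import EpmTrial, MazeTrial, ObjectTrial
from .ppi import build_ppi_graph
from .rescue import BASELINE, MODEL, TREATED, ExpressionStudy

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


DEFAULT_INGREDIENT_COLUMNS = {
    "herb": "herb",
    "ingredient": "ingredient",
    "ob": "ob",
    "dl": "dl",
    "caco2": "caco2",
}


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8").rename(
        columns=lambda c: c.strip()
    )


def read_ingredient_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[IngredientRecord]:
    """Parse a herb-ingredient table with ADME columns.

    ``columns`` maps the logical names (herb, ingredient, ob, dl, caco2)
    to the file's header names.  Missing columns raise FormatError naming
    the column; non-numeric ADME values raise FormatError with the
    offending row index (0-based, excluding the header).
    """
    cols = {**DEFAULT_INGREDIENT_COLUMNS, **(columns or {})}
    df = _read_table(path, sep=sep)
    for logical, header in cols.items():
        if header not in df.columns:
            raise FormatError(
                f"{path}: missing required column {header!r} (for {logical})"
            )
    records = []
    for idx, row in df.iterrows():
        adme = {}
        for key in ("ob", "dl", "caco2"):
            raw = row[cols[key]]
            try:
                adme[key] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {idx}: non-numeric {key} value {raw!r}"
                ) from None
        records.append(
            IngredientRecord(
                herb=str(row[cols["herb"]]).strip(),
                ingredient=str(row[cols["ingredient"]]).strip(),
                **adme,
            )
        )
    logger.info("read %d ingredient rows from %s", len(records), path)
    return records


def write_ingredient_table(
    records: Iterable[IngredientRecord], path: str | Path, sep: str = "\t"
) -> None:
    df = pd.DataFrame(
        [(r.herb, r.ingredient, r.ob, r.dl, r.caco2) for r in records],
        columns=["herb", "ingredient", "ob", "dl", "caco2"],
    )
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_string_edges(
    path: str | Path, score_min: float = 400, sep: str = "\t"
) -> nx.Graph:
    """Read a STRING-dialect scored edge list into a PPI graph.

    Expects three columns (two protein symbols and a combined score,
    0-1000); extra columns are ignored, header optional as long as the
    first two columns are names and the third numeric.  Malformed scores
    raise FormatError with the row index.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns, got {df.shape[1]}")
    rows = []
    for idx, row in df.iterrows():
        a, b, raw = row.iloc[0], row.iloc[1], row.iloc[2]
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: row {idx}: malformed combined score {raw!r}"
            ) from None
        rows.append((str(a), str(b), score))
    return build_ppi_graph(rows, score_min=score_min)


def write_string_edges(
    edges: pd.DataFrame | Iterable[tuple[str, str, float]],
    path: str | Path,
    sep: str = "\t",
) -> None:
    if not isinstance(edges, pd.DataFrame):
        edges = pd.DataFrame(
            list(edges), columns=["protein_a", "protein_b", "combined_score"]
        )
    edges.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_compound_target_table(
    path: str | Path, sep: str = "\t"
) -> list[tuple[str, str]]:
    """Two-column compound -> target pair table."""
    df = _read_table(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >= 2 columns")
    return [
        (str(a).strip(), str(b).strip())
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]


def write_compound_target_table(
    pairs: Iterable[tuple[str, str]], path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame(sorted(pairs), columns=["compound", "target"]).to_csv(
        path, sep=sep, index=False, encoding="utf-8"
    )


def read_group_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Two-column sample -> group assignment table."""
    df = _read_table(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected sample and group columns")
    return {
        str(s).strip(): str(g).strip()
        for s, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_expression_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    group_names: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> ExpressionStudy:
    """Read a genes x samples matrix and attach the group design.

    First column holds gene identifiers; the remaining columns are
    samples, each of which must be assigned by ``group_map`` to one of
    the design roles.  ``group_map`` may use either the role names
    (baseline/model/treated) directly or the study's own group names
    given in ``group_names`` (role -> name, e.g. baseline -> "sham").
    Duplicate genes, unassigned samples and negative values raise.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    names = group_names or {BASELINE: "sham", MODEL: "model", TREATED: "treated"}
    name_to_role = {v: k for k, v in names.items()}
    for role in (BASELINE, MODEL, TREATED):
        name_to_role.setdefault(role, role)
    groups: dict[str, str] = {}
    for sample in df.columns:
        if sample not in group_map:
            raise FormatError(f"{path}: sample {sample!r} missing from group map")
        label = group_map[sample]
        if label not in name_to_role:
            raise FormatError(
                f"{path}: sample {sample!r} has unknown group {label!r}"
            )
        groups[sample] = name_to_role[label]
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionStudy(values=values, groups=groups, group_names=names)


def write_expression_matrix(
    study: ExpressionStudy, matrix_path: str | Path,
    group_path: str | Path | None = None, sep: str = "\t",
) -> None:
    study.values.to_csv(matrix_path, sep=sep, index_label="gene",
                        encoding="utf-8")
    if group_path is not None:
        rows = [(s, study.group_names.get(study.groups[s], study.groups[s]))
                for s in study.values.columns]
        pd.DataFrame(rows, columns=["sample", "group"]).to_csv(
            group_path, sep=sep, index=False, encoding="utf-8"
        )


# --------------------------------------------------------------------------
# Behavioral trial logs


def read_maze_trials(path: str | Path, sep: str = "\t") -> list[MazeTrial]:
    """Long-format arm-entry log: columns mouse, arm, time_s."""
    df = _read_table(path, sep=sep)
    for col in ("mouse", "arm", "time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    trials = []
    for mouse, sub in df.groupby("mouse", sort=False):
        times = sub["time_s"].astype(float).tolist()
        trials.append(
            MazeTrial(mouse=str(mouse), entries=tuple(sub["arm"].str.strip()),
                      timestamps=tuple(times))
        )
    return trials


def write_maze_trials(
    trials: Iterable[MazeTrial], path: str | Path, sep: str = "\t"
) -> None:
    rows = [
        (t.mouse, arm, ts)
        for t in trials
        for arm, ts in zip(t.entries, t.timestamps)
    ]
    pd.DataFrame(rows, columns=["mouse", "arm", "time_s"]).to_csv(
        path, sep=sep, index=False, encoding="utf-8"
    )


def read_object_trials(path: str | Path, sep: str = "\t") -> list[ObjectTrial]:
    """Per-mouse novel/familiar exploration table."""
    df = _read_table(path, sep=sep)
    for col in ("mouse", "novel_time_s", "familiar_time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        ObjectTrial(
            mouse=str(row["mouse"]),
            novel_time=float(row["novel_time_s"]),
            familiar_time=float(row["familiar_time_s"]),
            distance=float(row.get("distance", 0.0) or 0.0),
        )
        for _, row in df.iterrows()
    ]


def write_object_trials(
    trials: Iterable[ObjectTrial], path: str | Path, sep: str = "\t"
) -> None:
    rows = [(t.mouse, t.novel_time, t.familiar_time, t.distance)
            for t in trials]
    pd.DataFrame(
        rows, columns=["mouse", "novel_time_s", "familiar_time_s", "distance"]
    ).to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_epm_trials(path: str | Path, sep: str = "\t") -> list[EpmTrial]:
    """Per-mouse elevated-plus-maze arm entry/duration table."""
    df = _read_table(path, sep=sep)
    for col in ("mouse", "closed_entries", "closed_time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        EpmTrial(
            mouse=str(row["mouse"]),
            closed_entries=int(float(row["closed_entries"])),
            closed_time=float(row["closed_time_s"]),
            open_entries=int(float(row.get("open_entries", 0) or 0)),
            open_time=float(row.get("open_time_s", 0.0) or 0.0),
        )
        for _, row in df.iterrows()
    ]


def write_epm_trials(
    trials: Iterable[EpmTrial], path: str | Path, sep: str = "\t"
) -> None:
    rows = [(t.mouse, t.closed_entries, t.closed_time, t.open_entries,
             t.open_time) for t in trials]
    pd.DataFrame(
        rows,
        columns=["mouse", "closed_entries", "closed_time_s", "open_entries",
                 "open_time_s"],
    ).to_csv(path, sep=sep, index=False, encoding="utf-8")
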
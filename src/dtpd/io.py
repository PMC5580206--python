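"""CSV readers/writers with strict, row-numbered validation.

All files are comma-separated UTF-8 with a required header. Row numbers in
error messages are 1-based file line numbers (header = line 1). Every writer
produces a file the matching reader parses back to an equal dataset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .concept_mapping import (
    ClusterSolution,
    MapConfiguration,
    RatingDataset,
    SimilarityMatrix,
    SortingDataset,
)
from .decision_tool import PatientRecord, ToolDecision, normalize_answer
from .errors import RecordValidationError

SORT_COLUMNS = ["sorter_id", "item_id", "pile"]
RATING_COLUMNS = ["rater_id", "item_id", "rating"]
PATIENT_COLUMNS = (
    ["centre_id", "therapist_id"]
    + [f"c{i}" for i in range(1, 8)]
    + ["q8", "clinical_judgement"]
)

__all__ = [
    "read_sorts",
    "write_sorts",
    "read_ratings",
    "write_ratings",
    "read_patients",
    "write_patients",
    "read_similarity",
    "write_similarity",
    "read_map",
    "write_map",
    "write_clusters",
    "write_decisions",
    "write_report",
]


def _load(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise RecordValidationError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise RecordValidationError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def read_sorts(path: str | Path) -> SortingDataset:
    df = _load(path, SORT_COLUMNS)
    assignment: dict[tuple[str, str], str] = {}
    items: dict[str, None] = {}
    sorters: dict[str, None] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        sorter, item, pile = row["sorter_id"], row["item_id"], row["pile"]
        if not sorter or not item or not pile:
            raise RecordValidationError(f"row {line}: empty field in sort record")
        if (sorter, item) in assignment:
            raise RecordValidationError(
                f"row {line}: duplicate assignment for sorter {sorter!r}, item {item!r}"
            )
        assignment[(sorter, item)] = pile
        items.setdefault(item)
        sorters.setdefault(sorter)
    return SortingDataset(
        items=tuple(items), sorters=tuple(sorters), assignment=assignment
    )


def write_sorts(sorts: SortingDataset, path: str | Path) -> None:
    rows = [
        {"sorter_id": s, "item_id": i, "pile": sorts.assignment[(s, i)]}
        for s in sorts.sorters
        for i in sorts.items
    ]
    pd.DataFrame(rows, columns=SORT_COLUMNS).to_csv(path, index=False)


def read_ratings(path: str | Path) -> RatingDataset:
    df = _load(path, RATING_COLUMNS)
    ratings: dict[tuple[str, str], int] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        rater, item, raw = row["rater_id"], row["item_id"], row["rating"]
        if not rater or not item:
            raise RecordValidationError(f"row {line}: empty field in rating record")
        try:
            value = int(raw)
        except ValueError:
            raise RecordValidationError(
                f"row {line}: rating {raw!r} is not an integer"
            ) from None
        if not (1 <= value <= 6):
            raise RecordValidationError(f"row {line}: rating {value} outside [1, 6]")
        if (rater, item) in ratings:
            raise RecordValidationError(
                f"row {line}: duplicate rating for rater {rater!r}, item {item!r}"
            )
        ratings[(rater, item)] = value
    return RatingDataset(ratings=ratings)


def write_ratings(ratings: RatingDataset, path: str | Path) -> None:
    rows = [
        {"rater_id": r, "item_id": i, "rating": v}
        for (r, i), v in ratings.ratings.items()
    ]
    pd.DataFrame(rows, columns=RATING_COLUMNS).to_csv(path, index=False)


def read_patients(path: str | Path) -> list[PatientRecord]:
    df = _load(path, PATIENT_COLUMNS)
    records = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            answers = tuple(normalize_answer(row[f"c{i}"]) for i in range(1, 8))
            gate = normalize_answer(row["q8"])
            judged = normalize_answer(row["clinical_judgement"])
        except RecordValidationError as exc:
            raise RecordValidationError(f"row {line}: {exc}") from None
        if judged == "na":
            raise RecordValidationError(
                f"row {line}: clinical_judgement must be yes or no"
            )
        records.append(
            PatientRecord(
                centre_id=row["centre_id"],
                therapist_id=row["therapist_id"],
                answers=answers,
                gate_q8=gate,
                clinical_judgement=judged == "yes",
            )
        )
    if not records:
        raise RecordValidationError(f"{path}: no patient records")
    return records


def write_patients(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"centre_id": r.centre_id, "therapist_id": r.therapist_id}
        row.update({f"c{i + 1}": a for i, a in enumerate(r.answers)})
        row["q8"] = r.gate_q8
        row["clinical_judgement"] = "yes" if r.clinical_judgement else "no"
        rows.append(row)
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.counts, index=sim.items, columns=sim.items)
    df.index.name = "item_id"
    df.to_csv(path)


def read_similarity(path: str | Path, n_sorters: int | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    counts = df.to_numpy(dtype=int)
    n = int(counts[0, 0]) if n_sorters is None else n_sorters
    return SimilarityMatrix(items=tuple(df.columns), counts=counts, n_sorters=n)


def write_map(config: MapConfiguration, path: str | Path) -> None:
    """Coordinates as CSV; stress/seed metadata in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "item_id": config.items,
            "x": config.coords[:, 0],
            "y": config.coords[:, 1],
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "stress": config.stress,
        "seed": config.seed,
        "n_starts": config.n_starts,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_map(path: str | Path) -> MapConfiguration:
    path = Path(path)
    df = pd.read_csv(path, dtype={"item_id": str})
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return MapConfiguration(
        items=tuple(df["item_id"]),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        stress=meta["stress"],
        seed=meta["seed"],
        n_starts=meta["n_starts"],
    )


def write_clusters(solution: ClusterSolution, path: str | Path) -> None:
    rows = []
    for item, cluster in solution.labels.items():
        row = {"item_id": item, "cluster": cluster}
        if solution.item_bridging is not None:
            row["bridging"] = solution.item_bridging.get(item, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_decisions(
    records: Sequence[PatientRecord], decisions: Sequence[ToolDecision], path: str | Path
) -> None:
    rows = []
    for r, d in zip(records, decisions):
        rows.append(
            {
                "centre_id": r.centre_id,
                "therapist_id": r.therapist_id,
                "score": d.score,
                "passed_cutoff": d.passed_cutoff,
                "referral": d.referral,
                "clinical_judgement": "yes" if r.clinical_judgement else "no",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
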
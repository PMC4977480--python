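"""Edge-level accuracy metrics and benchmark sweeps.

The distance to the reference says how few edits the constructor needed;
the F-score says how much of the *true* target topology was recovered.
Precision is TP/(TP+FP) and recall TP/(TP+FN) over directed edges, with
the zero-denominator convention that an empty ratio is 0 (hence F-score 0
when there are no true positives).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .model import GeneNetwork, InputError
from .optimize import exhaustive, holistic, prioritized

logger = logging.getLogger(__name__)

_METHODS = {"holistic": holistic, "prioritized": prioritized, "exhaustive": exhaustive}


@dataclass(frozen=True)
class EvaluationMetrics:
    """Directed-edge confusion counts and derived scores."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


def f_score(inferred: GeneNetwork, truth: GeneNetwork) -> EvaluationMetrics:
    """Edge-level precision/recall/F-score of an inferred network."""
    if set(inferred.genes) != set(truth.genes):
        raise InputError("f_score requires networks on the same gene set")
    tp = len(inferred.edges & truth.edges)
    fp = len(inferred.edges - truth.edges)
    fn = len(truth.edges - inferred.edges)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return EvaluationMetrics(tp, fp, fn, precision, recall, score)


def run_sweep(
    manifest: dict | str | Path,
    root: str | Path | None = None,
    methods: tuple[str, ...] = ("holistic", "prioritized"),
    rankings: tuple[str, ...] = ("topsog",),
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Run every method x ranking over every benchmark item.

    ``manifest`` is a ``make_benchmark`` manifest (dict, or path to its
    ``manifest.json``); ``root`` is the artifact directory (defaults to the
    manifest file's directory).  Returns one tidy record per run with the
    distance to the reference, the F-score against the true target and the
    constructor-call count; per-item failures are recorded in the ``error``
    column and the sweep continues.
    """
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        root = root if root is not None else path.parent
        manifest = json.loads(path.read_text())
    if root is None:
        raise InputError("root directory required when passing a manifest dict")
    root = Path(root)
    for method in methods:
        if method not in _METHODS:
            raise InputError(f"unknown method {method!r}")

    records = []
    for item in manifest["targets"]:
        target = io.read_edge_tsv(root / item["path"])
        constraints = io.read_constraints(root / item["masked_path"], target)
        n_unknown = len(constraints.unknowns())
        for ref in item["references"]:
            reference = io.read_edge_tsv(root / ref["path"])
            for method in methods:
                for ranking in rankings:
                    record = {
                        "size": item["size"],
                        "replicate": item["replicate"],
                        "rate": ref["rate"],
                        "n_unknown": n_unknown,
                        "method": method,
                        "ranking": ranking,
                        "target_seed": item["seed"],
                        "reference_seed": ref["seed"],
                        "distance": None,
                        "f_score": None,
                        "constructor_calls": None,
                        "error": None,
                    }
                    try:
                        result = _METHODS[method](reference, constraints, ranking)
                        record["distance"] = result.distance_to_reference
                        record["f_score"] = f_score(result.network, target).f_score
                        record["constructor_calls"] = result.constructor_calls
                    except Exception as exc:  # noqa: BLE001 - sweep must go on
                        logger.error(
                            "sweep item failed (size=%s rep=%s rate=%s %s/%s): %s",
                            item["size"], item["replicate"], ref["rate"],
                            method, ranking, exc,
                        )
                        record["error"] = str(exc)
                    records.append(record)
    frame = pd.DataFrame.from_records(records)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame


def summarize(frame: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means over replicates per parameter cell."""
    ok = frame[frame["error"].isna()]
    return (
        ok.groupby(["size", "rate", "n_unknown", "method", "ranking"])
        .agg(
            mean_distance=("distance", "mean"),
            mean_f_score=("f_score", "mean"),
            mean_constructor_calls=("constructor_calls", "mean"),
            n=("distance", "size"),
        )
        .reset_index()
    )
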
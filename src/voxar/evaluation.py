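"""Experiment harnesses: leave-one-out comparison, database-size sweep,
unbalanced-database study and the missing-pathology probe.

All experiments run on cohorts sharing a grid (identity registration), so
diagnosis quality is attributable to the rating machinery rather than to a
registration engine.  The evaluator computes the LNCC of a target against
every needed atlas once and reuses it across all atlas subsets, which makes
repeated-subsampling designs cheap.

The repeated balanced subsampling used by :func:`size_sweep` draws, for each
repeat, a fixed number of atlases per database uniformly without replacement
(always excluding the target), stratified by condition, and is fully
deterministic under a master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .isa import fuse_weighted, rank_values, ranks_to_weights
from .rating import (
    build_rating_map,
    count_conditions,
    pool_rank_values,
    rating_histogram,
)
from .similarity import TargetMoments

__all__ = [
    "DiagnosisPlan",
    "CohortEvaluator",
    "ExperimentResult",
    "summarize",
    "loocv",
    "size_sweep",
    "imbalance_study",
    "missing_pathology_probe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosisPlan:
    """One diagnosis to run: a target and the atlas subset per condition."""

    target: int
    subsets: tuple[tuple[str, tuple[int, ...]], ...]
    methods: tuple[str, ...] = ("voxar",)
    tag: str = ""
    extra: tuple[tuple[str, object], ...] = ()

    @staticmethod
    def make(
        target: int,
        subsets: Mapping[str, Iterable[int]],
        methods: Sequence[str] = ("voxar",),
        tag: str = "",
        **extra,
    ) -> "DiagnosisPlan":
        return DiagnosisPlan(
            target=int(target),
            subsets=tuple(
                (c, tuple(sorted(int(i) for i in subsets[c]))) for c in sorted(subsets)
            ),
            methods=tuple(methods),
            tag=tag,
            extra=tuple(sorted(extra.items())),
        )


class CohortEvaluator:
    """Runs diagnosis plans over a cohort of labelled subjects.

    Subjects need ``condition``, ``image`` and ``true_mask`` attributes
    (e.g. :class:`~voxar.phantom.PhantomSubject`); all subjects must share
    one grid.
    """

    def __init__(
        self,
        subjects: Sequence,
        sigma_g: float = 2.0,
        T: int = 7,
        beta: float = 0.5,
        fusion_threshold: float = 0.8,
    ):
        if not subjects:
            raise ValueError("empty cohort")
        self.subjects = list(subjects)
        self.sigma_g = float(sigma_g)
        self.T = int(T)
        self.beta = float(beta)
        self.fusion_threshold = float(fusion_threshold)
        self.conditions = tuple(sorted({s.condition for s in subjects}))
        self.arrays = [np.asarray(s.image.data, dtype=np.float64) for s in subjects]
        self.masks = [np.asarray(s.true_mask.data) != 0 for s in subjects]
        shape = self.arrays[0].shape
        for a in self.arrays[1:]:
            if a.shape != shape:
                raise ValueError("all subjects must share one grid")
        self.shape = shape

    def indices_by_condition(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {c: [] for c in self.conditions}
        for i, s in enumerate(self.subjects):
            out[s.condition].append(i)
        return out

    # ------------------------------------------------------------------

    def _roi_for(self, subsets: Sequence[tuple[str, tuple[int, ...]]]) -> np.ndarray:
        """Refined mask fusion per condition, then cross-condition AND."""
        roi: Optional[np.ndarray] = None
        for _, ids in subsets:
            stack = np.zeros(self.shape, dtype=np.int32)
            for i in ids:
                stack += self.masks[i]
            fused = stack >= self.fusion_threshold * len(ids) - 1e-9
            roi = fused if roi is None else (roi & fused)
        assert roi is not None
        return roi

    def run(self, plans: Sequence[DiagnosisPlan]) -> pd.DataFrame:
        """Execute plans grouped by target, reusing per-target similarity."""
        rows: list[dict] = []
        by_target: dict[int, list[DiagnosisPlan]] = {}
        for p in plans:
            by_target.setdefault(p.target, []).append(p)

        for target_idx in sorted(by_target):
            target_plans = by_target[target_idx]
            needed = sorted({i for p in target_plans for _, ids in p.subsets for i in ids})
            tm = TargetMoments(self.arrays[target_idx], self.sigma_g)
            sims = {}
            for i in needed:
                m = tm.lncc_to(self.arrays[i])
                sims[i] = (m.values.ravel(), m.defined.ravel())
            target_flat = self.arrays[target_idx].ravel()
            for plan in target_plans:
                rows.extend(self._run_plan(plan, sims, target_flat))
            del sims
        return pd.DataFrame(rows)

    def _run_plan(self, plan, sims, target_flat) -> list[dict]:
        subject = self.subjects[plan.target]
        base = {
            "tag": plan.tag,
            "target_index": plan.target,
            "subject_id": getattr(subject, "subject_id", str(plan.target)),
            "true": subject.condition,
            **dict(plan.extra),
        }
        conds = tuple(c for c, _ in plan.subsets)
        roi = self._roi_for(plan.subsets)
        if not roi.any():
            return [
                {**base, "method": m, "predicted": None, "status": "empty_roi",
                 "correct": False, "separation": np.nan}
                for m in plan.methods
            ]
        idx = np.flatnonzero(roi.ravel())

        atlas_rows = [(ci, i) for ci, (_, ids) in enumerate(plan.subsets) for i in ids]
        values = np.stack([sims[i][0][idx] for _, i in atlas_rows])
        defined = np.stack([sims[i][1][idx] for _, i in atlas_rows])
        cond_idx = np.asarray([ci for ci, _ in atlas_rows])

        out = []
        for method in plan.methods:
            if method == "voxar":
                out.append(self._voxar_row(base, values, defined, cond_idx, conds))
            elif method == "isa":
                out.append(
                    self._isa_row(
                        base, values, defined, cond_idx, conds, atlas_rows, idx, target_flat
                    )
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        return out

    def _voxar_row(self, base, values, defined, cond_idx, conds) -> dict:
        pooled = pool_rank_values(values, defined, cond_idx, conds, self.T)
        rmap = build_rating_map(count_conditions(pooled))
        hist = rating_histogram(rmap)
        predicted = hist.argmax()
        return {
            **base,
            "method": "voxar",
            "predicted": predicted,
            "status": "ok" if predicted is not None else "refused",
            "correct": predicted == base["true"],
            "separation": np.nan if hist.separation is None else hist.separation,
            "histogram": dict(hist.percentages),
            "n_assigned": hist.n_assigned,
            "n_unassigned": hist.n_unassigned,
        }

    def _isa_row(
        self, base, values, defined, cond_idx, conds, atlas_rows, idx, target_flat
    ) -> dict:
        t = target_flat[idx]
        t_sd = t.std()
        if t_sd == 0:
            return {**base, "method": "isa", "predicted": None, "status": "flat_target",
                    "correct": False, "separation": np.nan}
        t_norm = (t - t.mean()) / t_sd
        scores: dict[str, float] = {}
        for ci, cond in enumerate(conds):
            rows = np.flatnonzero(cond_idx == ci)
            ranks = rank_values(values[rows], defined[rows])
            weights = ranks_to_weights(ranks, self.beta)
            stack = []
            for r in rows:
                j = self.arrays[atlas_rows[r][1]].ravel()[idx]
                sd = j.std()
                if sd == 0:
                    stack.append(np.zeros_like(j))
                else:
                    stack.append((j - j.mean()) / sd)
            fused, fdef = fuse_weighted(np.stack(stack), weights)
            x = t_norm[fdef]
            y = fused[fdef]
            xd, yd = x - x.mean(), y - y.mean()
            denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
            scores[cond] = float((xd * yd).sum() / denom) if denom > 0 else float("nan")
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        predicted = ordered[0][0]
        sep = (ordered[0][1] - ordered[1][1]) if len(ordered) > 1 else np.nan
        return {
            **base,
            "method": "isa",
            "predicted": predicted,
            "status": "ok",
            "correct": predicted == base["true"],
            "separation": sep,
            "ncc_scores": scores,
        }


# ----------------------------------------------------------------------
# result summaries


@dataclass
class ExperimentResult:
    """Per-target records plus the derived confusion matrix and metrics."""

    records: pd.DataFrame
    confusion: pd.DataFrame
    accuracy: float
    metrics: dict[str, float]
    labels: tuple[str, ...]


def _binary_metrics(records: pd.DataFrame, normal_label: str) -> dict[str, float]:
    """Pathological-vs-normal sensitivity/specificity/PPV/NPV.

    A refused diagnosis does not flag the subject as pathological, so a
    refused pathological target counts as a false negative.
    """
    true_path = records["true"] != normal_label
    pred_path = records["predicted"].notna() & (records["predicted"] != normal_label)
    tp = int((true_path & pred_path).sum())
    fn = int((true_path & ~pred_path).sum())
    tn = int((~true_path & ~pred_path).sum())
    fp = int((~true_path & pred_path).sum())

    def _ratio(a: int, b: int) -> float:
        return float("nan") if b == 0 else a / b

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def summarize(
    records: pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
    normal_label: str = "normal",
) -> ExperimentResult:
    """Row-normalised confusion matrix, overall accuracy and binary metrics."""
    if labels is None:
        labels = sorted(records["true"].unique())
    labels = tuple(labels)
    pred_labels = list(labels)
    if records["predicted"].isna().any():
        pred_labels = pred_labels + ["refused"]
    mat = pd.DataFrame(0.0, index=list(labels), columns=pred_labels)
    for true_label, grp in records.groupby("true"):
        n = len(grp)
        for pred, cnt in grp["predicted"].fillna("refused").value_counts().items():
            mat.loc[true_label, pred] = cnt / n
    accuracy = float(records["correct"].mean())
    return ExperimentResult(
        records=records,
        confusion=mat,
        accuracy=accuracy,
        metrics=_binary_metrics(records, normal_label),
        labels=labels,
    )


# ----------------------------------------------------------------------
# experiment designs


def _loocv_plans(
    evaluator: CohortEvaluator, methods: Sequence[str], tag: str = "loocv"
) -> list[DiagnosisPlan]:
    by_cond = evaluator.indices_by_condition()
    for cond, ids in by_cond.items():
        if len(ids) < 2:
            raise ValueError(f"condition {cond!r} has a single subject; cannot leave one out")
    plans = []
    for t in range(len(evaluator.subjects)):
        subsets = {c: [i for i in ids if i != t] for c, ids in by_cond.items()}
        plans.append(DiagnosisPlan.make(t, subsets, methods=methods, tag=tag))
    return plans


def loocv(
    subjects: Sequence,
    methods: Sequence[str] = ("voxar", "isa"),
    normal_label: str = "normal",
    **evaluator_kwargs,
) -> dict[str, ExperimentResult]:
    """Leave-one-out cross validation at the maximum database size.

    Each subject is diagnosed in turn with its own entry removed from its
    database and all other databases at full size.  Returns one
    :class:`ExperimentResult` per method.
    """
    evaluator = CohortEvaluator(subjects, **evaluator_kwargs)
    records = evaluator.run(_loocv_plans(evaluator, methods))
    return {
        m: summarize(records[records["method"] == m].reset_index(drop=True),
                     evaluator.conditions, normal_label)
        for m in methods
    }


def _subsample(
    rng: np.random.Generator, ids: Sequence[int], size: int, exclude: int
) -> list[int]:
    pool = [i for i in ids if i != exclude]
    if size > len(pool):
        raise ValueError(f"requested {size} atlases but only {len(pool)} available")
    return sorted(rng.choice(pool, size=size, replace=False).tolist())


def size_sweep(
    subjects: Sequence,
    sizes: Sequence[int],
    repeats: int = 10,
    methods: Sequence[str] = ("voxar",),
    seed: int = 0,
    **evaluator_kwargs,
) -> pd.DataFrame:
    """Balanced repeated subsampling over database sizes.

    For each size ``s`` and repeat, ``s`` atlases per database are drawn
    uniformly without replacement (excluding the target) and every subject
    is diagnosed.  Returns one row per (method, size, repeat) with the mean
    accuracy over targets; per-target records are attached under
    ``df.attrs["records"]``.  At ``s = N - 1`` a repeat reduces to the
    leave-one-out design.
    """
    evaluator = CohortEvaluator(subjects, **evaluator_kwargs)
    by_cond = evaluator.indices_by_condition()
    max_size = min(len(ids) for ids in by_cond.values()) - 1
    for s in sizes:
        if s > max_size:
            raise ValueError(f"size {s} exceeds available atlases per database ({max_size})")
    plans = []
    for s in sizes:
        for rep in range(repeats):
            rng = np.random.default_rng([int(seed), int(s), rep])
            for t in range(len(evaluator.subjects)):
                subsets = {c: _subsample(rng, ids, s, t) for c, ids in by_cond.items()}
                plans.append(
                    DiagnosisPlan.make(t, subsets, methods=methods, tag="sweep",
                                       size=int(s), repeat=rep)
                )
    records = evaluator.run(plans)
    per_run = (
        records.groupby(["method", "size", "repeat"], as_index=False)["correct"]
        .mean()
        .rename(columns={"correct": "accuracy"})
    )
    per_run.attrs["records"] = records
    return per_run


def imbalance_study(
    subjects: Sequence,
    correct_size: int,
    other_sizes: int | Sequence[int],
    repeats: int = 10,
    methods: Sequence[str] = ("voxar",),
    seed: int = 0,
    **evaluator_kwargs,
) -> pd.DataFrame:
    """Diagnosis accuracy with the target-condition database resized.

    The database of the target's own ("correct") condition holds
    ``correct_size`` atlases; the remaining databases hold ``other_sizes``
    (a scalar or one size per remaining condition, in sorted label order).
    ``correct_size == other_sizes`` reproduces a balanced subsampling run.
    """
    evaluator = CohortEvaluator(subjects, **evaluator_kwargs)
    by_cond = evaluator.indices_by_condition()
    plans = []
    for rep in range(repeats):
        rng = np.random.default_rng([int(seed), 7_001, rep])
        for t, subject in enumerate(evaluator.subjects):
            others = [c for c in evaluator.conditions if c != subject.condition]
            if np.isscalar(other_sizes):
                per_other = {c: int(other_sizes) for c in others}
            else:
                if len(other_sizes) != len(others):
                    raise ValueError(
                        f"{len(others)} non-target databases but {len(other_sizes)} sizes given"
                    )
                per_other = dict(zip(others, [int(s) for s in other_sizes]))
            subsets = {
                subject.condition: _subsample(rng, by_cond[subject.condition], correct_size, t)
            }
            for c in others:
                subsets[c] = _subsample(rng, by_cond[c], per_other[c], t)
            plans.append(
                DiagnosisPlan.make(
                    t, subsets, methods=methods, tag="imbalance",
                    correct_size=int(correct_size), repeat=rep,
                )
            )
    records = evaluator.run(plans)
    per_run = (
        records.groupby(["method", "repeat"], as_index=False)["correct"]
        .mean()
        .rename(columns={"correct": "accuracy"})
    )
    per_run.attrs["records"] = records
    return per_run


def missing_pathology_probe(
    subjects: Sequence,
    held_out_condition: str,
    methods: Sequence[str] = ("voxar",),
    **evaluator_kwargs,
) -> pd.DataFrame:
    """Diagnose targets of a condition absent from the atlas databases.

    Targets of ``held_out_condition`` are diagnosed against the databases of
    the remaining conditions; every remaining-condition subject is also
    diagnosed leave-one-out as a known-condition baseline.  The returned
    records carry ``probe`` = ``"held_out"`` or ``"known"``; comparing the
    histogram ``separation`` of the two groups quantifies the confidence
    drop in the presence of an unrepresented pathology.
    """
    evaluator = CohortEvaluator(subjects, **evaluator_kwargs)
    by_cond = evaluator.indices_by_condition()
    if held_out_condition not in by_cond:
        raise ValueError(f"no subjects with condition {held_out_condition!r}")
    known = {c: ids for c, ids in by_cond.items() if c != held_out_condition}
    if len(known) < 2:
        raise ValueError("fewer than two databases remain after holding out")
    plans = []
    for t in by_cond[held_out_condition]:
        plans.append(
            DiagnosisPlan.make(t, known, methods=methods, tag="missing", probe="held_out")
        )
    for c, ids in known.items():
        if len(ids) < 2:
            raise ValueError(f"condition {c!r} has a single subject; cannot leave one out")
        for t in ids:
            subsets = {cc: [i for i in cids if i != t] for cc, cids in known.items()}
            plans.append(
                DiagnosisPlan.make(t, subsets, methods=methods, tag="missing", probe="known")
            )
    return evaluator.run(plans)
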
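"""Synthetic paired MRI/CEM diagnostic cohorts.

The study population this generator emulates is a single-centre breast
cohort of 68 lesions — 47 biopsy-confirmed malignant and 21 benign — each
read on both breast MRI and contrast-enhanced mammography (CEM) with the
five Kaiser descriptors.  No per-lesion data are deposited, so the
generator works from a :class:`FixtureSpec`: per-group, per-modality
Kaiser-score frequency tables.  The shipped default table was calibrated
by integer search so that the exact-count cohort reproduces the published
summary statistics — per-group score medians and IQRs, the Youden and
100%-NPV operating points with their sensitivity/specificity/PPV/NPV, and
the pair-counting AUCs (0.951 MRI, 0.940 CEM) — simultaneously.

Two generation modes are deliberately distinct: :func:`exact_count_cohort`
emits the calibrated score multisets verbatim (deterministic evaluation
fixtures), while :func:`sample_cohort` draws scores multinomially from the
normalized frequencies (seeded stochastic cohorts for robustness and
power work).  In both modes each record is made internally consistent:
descriptor vectors are drawn from the flowchart paths that reach the
required score leaf, and CEM ROI density pairs are drawn so that the
kinetics classifier recovers the record's delayed-phase descriptor.
MRI and CEM scores are paired rank-concordantly within each truth group;
no per-lesion cross-modality table exists to calibrate against.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .diagnostics import auc, confusion_at_cutoff, summarize_scores, youden_optimal_cutoff, clinical_cutoff_100npv
from .flowchart import (
    FEATURE_VALUES,
    SCORE_MAX,
    SCORE_MIN,
    DecisionTree,
    LesionFeatures,
    load_builtin_tree,
)
from .kinetics import DEFAULT_KINETICS_THRESHOLD, ROIPair, classify_enhancement

__all__ = [
    "GROUPS",
    "MODALITIES",
    "FixtureSpec",
    "ModalityAssessment",
    "CohortRecord",
    "default_fixture",
    "load_fixture",
    "exact_count_cohort",
    "sample_cohort",
    "features_from_score",
    "roi_pair_from_curve_type",
    "cohort_to_frame",
    "calibration_certificate",
]

GROUPS = ("malignant", "benign")
MODALITIES = ("mri", "cem")

DEFAULT_BASELINE_RANGE = (1800, 2400)
DEFAULT_DELTA_RANGE = (11, 60)


@dataclass(frozen=True)
class FixtureSpec:
    """Per-(group, modality) Kaiser-score frequency tables.

    ``tables[(group, modality)]`` maps score -> lesion count; counts must
    sum to the group size and scores must lie in [1, 12].
    """

    n_malignant: int
    n_benign: int
    tables: Mapping[tuple[str, str], Mapping[int, int]]

    def __post_init__(self) -> None:
        if self.n_malignant <= 0 or self.n_benign <= 0:
            raise ValueError("group sizes must be positive")
        sizes = {"malignant": self.n_malignant, "benign": self.n_benign}
        for group in GROUPS:
            for modality in MODALITIES:
                try:
                    table = self.tables[(group, modality)]
                except KeyError:
                    raise ValueError(f"missing table for ({group}, {modality})") from None
                for score, count in table.items():
                    if not SCORE_MIN <= score <= SCORE_MAX:
                        raise ValueError(f"score {score} outside [1, 12] in {group}/{modality}")
                    if count < 0:
                        raise ValueError(f"negative count in {group}/{modality}")
                if sum(table.values()) != sizes[group]:
                    raise ValueError(
                        f"{group}/{modality} counts sum to {sum(table.values())}, "
                        f"expected {sizes[group]}"
                    )

    def scores(self, group: str, modality: str) -> list[int]:
        """The score multiset of one (group, modality), sorted ascending."""
        table = self.tables[(group, modality)]
        out: list[int] = []
        for score in sorted(table):
            out.extend([score] * table[score])
        return out

    def to_json_dict(self) -> dict:
        return {
            "n_malignant": self.n_malignant,
            "n_benign": self.n_benign,
            "tables": {
                group: {
                    modality: {str(k): v for k, v in sorted(self.tables[(group, modality)].items())}
                    for modality in MODALITIES
                }
                for group in GROUPS
            },
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "FixtureSpec":
        tables = {
            (group, modality): {int(k): int(v) for k, v in doc["tables"][group][modality].items()}
            for group in GROUPS
            for modality in MODALITIES
        }
        return cls(
            n_malignant=int(doc["n_malignant"]),
            n_benign=int(doc["n_benign"]),
            tables=tables,
        )

    def sha256(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass(frozen=True)
class ModalityAssessment:
    score: int
    features: LesionFeatures


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic lesion: truth label, both modality readings, and the
    CEM ROI density pair consistent with the CEM delayed-phase descriptor."""

    lesion_id: str
    truth: str
    mri: ModalityAssessment
    cem: ModalityAssessment
    roi: ROIPair


def default_fixture() -> FixtureSpec:
    """The shipped calibrated fixture (47 malignant + 21 benign lesions).

    Its calibration checklist can be recomputed with
    :func:`calibration_certificate`.
    """
    ref = resources.files("kscem.data") / "fixture_default.json"
    return FixtureSpec.from_json_dict(json.loads(ref.read_text()))


def load_fixture(source: Union[str, Path, Mapping]) -> FixtureSpec:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return FixtureSpec.from_json_dict(json.load(fh))
    return FixtureSpec.from_json_dict(source)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _paths_by_score(tree: DecisionTree) -> dict[int, list[dict[str, str]]]:
    by_score: dict[int, list[dict[str, str]]] = {}
    for bound, leaf in tree.paths():
        by_score.setdefault(leaf, []).append(bound)
    return by_score


def _draw_features(
    score: int,
    by_score: Mapping[int, list[dict[str, str]]],
    rng: np.random.Generator,
) -> LesionFeatures:
    candidates = by_score.get(score)
    if not candidates:
        raise ValueError(f"score {score} is not a leaf of this tree")
    bound = candidates[int(rng.integers(len(candidates)))]
    values = {}
    for name, allowed in FEATURE_VALUES.items():
        values[name] = bound.get(name) or allowed[int(rng.integers(len(allowed)))]
    return LesionFeatures(**values)


def features_from_score(
    score: int, tree: DecisionTree, seed
) -> LesionFeatures:
    """Draw a descriptor vector that the flowchart scores as ``score``.

    One root-to-leaf path with the requested leaf value is selected
    uniformly (seeded); descriptors tested on the path are fixed by it and
    the remaining descriptors are drawn uniformly from their categories.
    By construction ``tree.score(result) == score``.
    """
    return _draw_features(score, _paths_by_score(tree), _as_rng(seed))


def roi_pair_from_curve_type(
    curve: str,
    seed,
    baseline_range: tuple[int, int] = DEFAULT_BASELINE_RANGE,
    delta_range: tuple[int, int] = DEFAULT_DELTA_RANGE,
    threshold: float = DEFAULT_KINETICS_THRESHOLD,
) -> ROIPair:
    """Draw an ROI density pair whose kinetics classify as ``curve``.

    The initial mean is uniform on ``baseline_range`` (device units, a
    plausible recombined-image scale bracketing published worked examples
    around 2150-2180); the delayed mean adds a density change drawn from
    ``+delta_range`` (persistent), ``-delta_range`` (washout), or the
    closed plateau interval ``[-threshold, +threshold]``.
    """
    if curve not in ("persistent", "plateau", "washout"):
        raise ValueError(f"unknown curve type {curve!r}")
    lo, hi = baseline_range
    dlo, dhi = delta_range
    if lo > hi or dlo > dhi:
        raise ValueError("ranges must be (low, high) with low <= high")
    if dlo <= threshold:
        raise ValueError(
            f"delta_range minimum {dlo} must exceed the classification "
            f"threshold {threshold}"
        )
    rng = _as_rng(seed)
    base = int(rng.integers(lo, hi + 1))
    if curve == "persistent":
        d = int(rng.integers(dlo, dhi + 1))
    elif curve == "washout":
        d = -int(rng.integers(dlo, dhi + 1))
    else:
        t = int(threshold)
        d = int(rng.integers(-t, t + 1))
    return ROIPair(initial_mean=float(base), delayed_mean=float(base + d))


def _build_records(
    mal_mri: Sequence[int],
    mal_cem: Sequence[int],
    ben_mri: Sequence[int],
    ben_cem: Sequence[int],
    mri_tree: DecisionTree,
    cem_tree: DecisionTree,
    rng: np.random.Generator,
) -> list[CohortRecord]:
    records: list[CohortRecord] = []
    mri_paths = _paths_by_score(mri_tree)
    cem_paths = _paths_by_score(cem_tree)
    groups = [
        ("malignant", "M", sorted(mal_mri), sorted(mal_cem)),
        ("benign", "B", sorted(ben_mri), sorted(ben_cem)),
    ]
    for truth, prefix, mri_scores, cem_scores in groups:
        width = len(str(len(mri_scores)))
        # sorting both multisets pairs MRI and CEM rank-concordantly
        for i, (sm, sc) in enumerate(zip(mri_scores, cem_scores), start=1):
            fm = _draw_features(sm, mri_paths, rng)
            fc = _draw_features(sc, cem_paths, rng)
            roi = roi_pair_from_curve_type(fc.delayed_phase, rng)
            records.append(
                CohortRecord(
                    lesion_id=f"{prefix}{i:0{width}d}",
                    truth=truth,
                    mri=ModalityAssessment(score=sm, features=fm),
                    cem=ModalityAssessment(score=sc, features=fc),
                    roi=roi,
                )
            )
    return records


def exact_count_cohort(
    spec: FixtureSpec | None = None,
    seed: int = 0,
    *,
    mri_tree: DecisionTree | None = None,
    cem_tree: DecisionTree | None = None,
) -> list[CohortRecord]:
    """Deterministically emit exactly the score multisets of ``spec``.

    The score columns are fully determined by the spec; the seed only
    selects which flowchart path realizes each score and the ROI draws.
    """
    spec = spec or default_fixture()
    mri_tree = mri_tree or load_builtin_tree("mri")
    cem_tree = cem_tree or load_builtin_tree("cem")
    rng = _as_rng(seed)
    return _build_records(
        spec.scores("malignant", "mri"),
        spec.scores("malignant", "cem"),
        spec.scores("benign", "mri"),
        spec.scores("benign", "cem"),
        mri_tree,
        cem_tree,
        rng,
    )


def sample_cohort(
    spec: FixtureSpec | None = None,
    seed: int = 0,
    n_malignant: int = 47,
    n_benign: int = 21,
    *,
    mri_tree: DecisionTree | None = None,
    cem_tree: DecisionTree | None = None,
) -> list[CohortRecord]:
    """Draw a stochastic cohort from the spec's normalized frequencies."""
    if n_malignant <= 0 or n_benign <= 0:
        raise ValueError("group sizes must be positive")
    spec = spec or default_fixture()
    mri_tree = mri_tree or load_builtin_tree("mri")
    cem_tree = cem_tree or load_builtin_tree("cem")
    rng = _as_rng(seed)

    def draw(group: str, modality: str, n: int) -> list[int]:
        table = spec.tables[(group, modality)]
        scores = np.array(sorted(table))
        p = np.array([table[s] for s in sorted(table)], dtype=float)
        return [int(s) for s in rng.choice(scores, size=n, p=p / p.sum())]

    return _build_records(
        draw("malignant", "mri", n_malignant),
        draw("malignant", "cem", n_malignant),
        draw("benign", "mri", n_benign),
        draw("benign", "cem", n_benign),
        mri_tree,
        cem_tree,
        rng,
    )


def cohort_to_frame(
    records: Sequence[CohortRecord], with_scores: bool = False
) -> pd.DataFrame:
    """Long-format lesion table: one row per (lesion, modality).

    Columns follow the lesion-table CSV dialect (lesion_id, modality, the
    five descriptors, truth) plus roi_initial/roi_delayed on CEM rows;
    ``with_scores`` appends the score column.
    """
    rows = []
    for rec in records:
        for modality in MODALITIES:
            assess: ModalityAssessment = getattr(rec, modality)
            row = {
                "lesion_id": rec.lesion_id,
                "modality": modality,
                **assess.features.as_dict(),
                "truth": rec.truth,
                "roi_initial": rec.roi.initial_mean if modality == "cem" else None,
                "roi_delayed": rec.roi.delayed_mean if modality == "cem" else None,
            }
            if with_scores:
                row["score"] = assess.score
            rows.append(row)
    return pd.DataFrame(rows)


#: Published summary statistics the default fixture is calibrated to.
CALIBRATION_CONSTRAINTS = {
    "malignant_mri_summary": (9.0, 8.0, 9.0),
    "malignant_cem_summary": (9.0, 8.0, 9.0),
    "benign_mri_summary": (3.0, 2.0, 3.0),
    "youden_cutoff": {"mri": 6, "cem": 6},
    "clinical_cutoff": {"mri": 3, "cem": 3},
    "confusion_at_youden": {"mri": (42, 1, 5, 20), "cem": (41, 1, 6, 20)},
    "confusion_at_clinical": {"mri": (47, 15, 0, 6), "cem": (47, 15, 0, 6)},
    "auc_pair_fraction": {"mri": (938.5, 987), "cem": (928.0, 987)},
    "auc_rounded": {"mri": 0.951, "cem": 0.940},
}


def calibration_certificate(spec: FixtureSpec | None = None) -> dict:
    """Recompute the fixture's calibration checklist.

    Returns ``{check_name: {"expected", "observed", "ok"}}`` covering the
    per-group score summaries, both operating cut-offs, the confusion
    matrices at each, and the pair-counting AUC fractions.
    """
    spec = spec or default_fixture()
    out: dict[str, dict] = {}

    def record(name: str, expected, observed) -> None:
        out[name] = {"expected": expected, "observed": observed, "ok": expected == observed}

    c = CALIBRATION_CONSTRAINTS
    for name, (group, modality) in {
        "malignant_mri_summary": ("malignant", "mri"),
        "malignant_cem_summary": ("malignant", "cem"),
        "benign_mri_summary": ("benign", "mri"),
    }.items():
        s = summarize_scores(spec.scores(group, modality))
        record(name, c[name], (s.median, s.iqr_low, s.iqr_high))

    for modality in MODALITIES:
        scores = spec.scores("malignant", modality) + spec.scores("benign", modality)
        labels = ["malignant"] * spec.n_malignant + ["benign"] * spec.n_benign
        record(f"youden_cutoff_{modality}", c["youden_cutoff"][modality],
               youden_optimal_cutoff(scores, labels))
        record(f"clinical_cutoff_{modality}", c["clinical_cutoff"][modality],
               clinical_cutoff_100npv(scores, labels))
        cm_y = confusion_at_cutoff(scores, labels, c["youden_cutoff"][modality])
        record(f"confusion_at_youden_{modality}", c["confusion_at_youden"][modality],
               (cm_y.tp, cm_y.fp, cm_y.fn, cm_y.tn))
        cm_c = confusion_at_cutoff(scores, labels, c["clinical_cutoff"][modality])
        record(f"confusion_at_clinical_{modality}", c["confusion_at_clinical"][modality],
               (cm_c.tp, cm_c.fp, cm_c.fn, cm_c.tn))
        a = auc(scores, labels)
        num, den = c["auc_pair_fraction"][modality]
        out[f"auc_{modality}"] = {
            "expected": num / den,
            "observed": a,
            "rounds_to": c["auc_rounded"][modality],
            "ok": abs(a - num / den) < 1e-12
            and float(round(a, 3)) == c["auc_rounded"][modality],
        }
    return out
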
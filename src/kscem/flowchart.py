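"""Kaiser-score decision trees over the five lesion descriptors.

The Kaiser score is a clinical decision rule for contrast-enhanced breast
imaging: five morphological/kinetic descriptors (spiculation "root sign",
delayed-phase kinetics, margins, internal enhancement pattern, diffuse
oedema) are fed through a fixed flowchart that terminates in an integer
score from 1 to 12.  Higher scores mean higher likelihood of malignancy;
a score strictly greater than 4 triggers a biopsy recommendation.

Trees are data, not code: a flowchart is loaded from a small JSON document
(``{"node": {"feature": ..., "branches": {...}}}`` / ``{"leaf": {"score": n}}``)
so that variants — the MRI original, its contrast-enhanced mammography (CEM)
adaptation, or future flowcharts with extra moderators — plug in without
touching the scorer.  Two documents ship with the package
(``kaiser_mri.json``, ``kaiser_cem.json``); the CEM variant is identical in
topology and leaf values and differs only in how the oedema descriptor is
read (diffuse ipsilateral oedema only, since CEM cannot depict perifocal
oedema).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence, Union

__all__ = [
    "FEATURE_VALUES",
    "SCORE_MIN",
    "SCORE_MAX",
    "DEFAULT_BIOPSY_THRESHOLD",
    "DEFAULT_BIRADS_BANDS",
    "CEM_OEDEMA_CRITERION",
    "LesionFeatures",
    "Leaf",
    "Node",
    "DecisionTree",
    "KaiserScore",
    "TreeValidationError",
    "TreeSchemaError",
    "LeafScoreError",
    "BranchCoverageError",
    "DuplicateFeatureError",
    "ScoringError",
    "load_tree",
    "load_builtin_tree",
    "score_lesion",
    "recommend_biopsy",
    "adapt_tree_for_cem",
    "map_to_birads",
]

#: Descriptor lexicon: each feature and its admissible categories.
FEATURE_VALUES: dict[str, tuple[str, ...]] = {
    "root_sign": ("absent", "present"),
    "delayed_phase": ("persistent", "plateau", "washout"),
    "margins": ("circumscribed", "irregular"),
    "internal_enhancement": ("homogeneous_centrifugal", "inhomogeneous_centripetal"),
    "oedema": ("absent", "present"),
}

SCORE_MIN = 1
SCORE_MAX = 12
DEFAULT_BIOPSY_THRESHOLD = 4

CEM_OEDEMA_CRITERION = "diffuse ipsilateral breast oedema"

#: Non-normative default mapping from Kaiser score bands to BI-RADS
#: categories.  Every score above the biopsy threshold lands in BI-RADS 4
#: or 5; the mapping is configuration, not part of the decision rule.
DEFAULT_BIRADS_BANDS: tuple[tuple[int, int, str], ...] = (
    (1, 1, "2"),
    (2, 4, "3"),
    (5, 7, "4"),
    (8, 12, "5"),
)


class TreeValidationError(ValueError):
    """A flowchart document violates the tree contract."""


class TreeSchemaError(TreeValidationError):
    """Document structure does not match the node/leaf schema."""


class LeafScoreError(TreeValidationError):
    """A leaf carries a score outside [1, 12] or a non-integer."""


class BranchCoverageError(TreeValidationError):
    """A node's branches do not cover its feature's values exactly."""


class DuplicateFeatureError(TreeValidationError):
    """A root-to-leaf path tests the same feature twice."""


class ScoringError(ValueError):
    """A lesion could not be routed through the flowchart."""


@dataclass(frozen=True)
class LesionFeatures:
    """The five Kaiser descriptors of one lesion in one modality.

    All five fields are required and must take one of the categories in
    :data:`FEATURE_VALUES`; the scorer accepts no missing values.
    """

    root_sign: str
    delayed_phase: str
    margins: str
    internal_enhancement: str
    oedema: str

    def __post_init__(self) -> None:
        for name, allowed in FEATURE_VALUES.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(
                    f"{name}={value!r} is not one of {sorted(allowed)}"
                )

    def as_dict(self) -> dict[str, str]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Leaf:
    score: int


@dataclass(frozen=True)
class Node:
    feature: str
    branches: Mapping[str, Union["Node", Leaf]]


@dataclass(frozen=True)
class KaiserScore:
    """A scored lesion: flowchart value, management recommendation, band."""

    value: int
    biopsy_recommended: bool
    birads_category: str | None = None


@dataclass(frozen=True)
class DecisionTree:
    """A validated Kaiser-score flowchart.

    Attributes
    ----------
    root : Node or Leaf
        Branching structure; every internal node names one descriptor and
        has exactly one child per category of that descriptor.
    variant : str
        ``"mri"`` or ``"cem"``.
    oedema_criterion : str
        How the oedema descriptor is to be read on this modality.
    """

    root: Node | Leaf
    variant: str = "mri"
    oedema_criterion: str = ""

    def score(self, features: LesionFeatures) -> int:
        """Route ``features`` to the unique leaf and return its score."""
        node = self.root
        trail: list[str] = []
        while isinstance(node, Node):
            value = getattr(features, node.feature, None)
            if value is None or value not in node.branches:
                raise ScoringError(
                    f"no value for feature {node.feature!r} at node "
                    f"{' -> '.join(trail) or 'root'}"
                )
            trail.append(f"{node.feature}={value}")
            node = node.branches[value]
        return node.score

    def paths(self) -> list[tuple[dict[str, str], int]]:
        """All root-to-leaf paths as (tested-feature assignment, score)."""
        out: list[tuple[dict[str, str], int]] = []

        def walk(node: Node | Leaf, bound: dict[str, str]) -> None:
            if isinstance(node, Leaf):
                out.append((dict(bound), node.score))
                return
            for value, child in node.branches.items():
                walk(child, {**bound, node.feature: value})

        walk(self.root, {})
        return out

    def leaf_scores(self) -> frozenset[int]:
        return frozenset(score for _, score in self.paths())


def _parse_node(doc: object, path: str, seen: frozenset[str]) -> Node | Leaf:
    if not isinstance(doc, Mapping):
        raise TreeSchemaError(f"{path}: expected a mapping, got {type(doc).__name__}")
    keys = set(doc)
    if keys == {"leaf"}:
        leaf = doc["leaf"]
        if not isinstance(leaf, Mapping) or set(leaf) != {"score"}:
            raise TreeSchemaError(f"{path}: leaf must be {{'score': int}}")
        score = leaf["score"]
        if not isinstance(score, int) or isinstance(score, bool) or not (
            SCORE_MIN <= score <= SCORE_MAX
        ):
            raise LeafScoreError(
                f"{path}: leaf score {score!r} outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        return Leaf(score)
    if keys == {"node"}:
        spec = doc["node"]
        if not isinstance(spec, Mapping) or set(spec) != {"feature", "branches"}:
            raise TreeSchemaError(
                f"{path}: node must be {{'feature': ..., 'branches': ...}}"
            )
        feature = spec["feature"]
        if feature not in FEATURE_VALUES:
            raise TreeSchemaError(f"{path}: unknown feature {feature!r}")
        if feature in seen:
            raise DuplicateFeatureError(
                f"{path}: feature {feature!r} already tested on this path"
            )
        branches = spec["branches"]
        if not isinstance(branches, Mapping):
            raise TreeSchemaError(f"{path}: branches must be a mapping")
        expected = set(FEATURE_VALUES[feature])
        got = set(branches)
        if got != expected:
            missing = expected - got
            extra = got - expected
            detail = []
            if missing:
                detail.append(f"unreachable value(s) {sorted(missing)}")
            if extra:
                detail.append(f"unknown value(s) {sorted(extra)}")
            raise BranchCoverageError(
                f"{path}: branches of {feature!r} invalid: {'; '.join(detail)}"
            )
        children = {
            value: _parse_node(child, f"{path}/{feature}={value}", seen | {feature})
            for value, child in branches.items()
        }
        return Node(feature, children)
    raise TreeSchemaError(
        f"{path}: expected exactly one of 'node' or 'leaf', got keys {sorted(keys)}"
    )


def load_tree(source: Union[str, Path, Mapping]) -> DecisionTree:
    """Load and validate a flowchart document.

    ``source`` may be a mapping already parsed from JSON, or a path to a
    JSON file.  The document is either a bare tree (``{"node": ...}`` /
    ``{"leaf": ...}``) or wrapped with metadata
    ``{"variant": ..., "oedema_criterion": ..., "tree": ...}``.

    Raises a specific :class:`TreeValidationError` subclass naming the
    offending node for schema violations, out-of-range leaf scores,
    uncovered/unknown branch values, and duplicated features on a path.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    if not isinstance(doc, Mapping):
        raise TreeSchemaError("tree document must be a mapping")
    variant = "mri"
    criterion = ""
    if "tree" in doc:
        variant = doc.get("variant", "mri")
        criterion = doc.get("oedema_criterion", "")
        body = doc["tree"]
    else:
        body = doc
    root = _parse_node(body, "root", frozenset())
    return DecisionTree(root=root, variant=variant, oedema_criterion=criterion)


def load_builtin_tree(variant: str) -> DecisionTree:
    """Load a shipped flowchart: ``"mri"`` or ``"cem"``."""
    if variant not in ("mri", "cem"):
        raise ValueError(f"unknown built-in tree variant {variant!r}")
    ref = resources.files("kscem.data") / f"kaiser_{variant}.json"
    return load_tree(json.loads(ref.read_text()))


def recommend_biopsy(score: int, threshold: int = DEFAULT_BIOPSY_THRESHOLD) -> bool:
    """True iff ``score`` strictly exceeds ``threshold`` (default 4)."""
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return score > threshold


def _validate_bands(bands: Sequence[tuple[int, int, str]]) -> None:
    ordered = sorted(bands, key=lambda b: b[0])
    if not ordered or ordered[0][0] != SCORE_MIN or ordered[-1][1] != SCORE_MAX:
        raise ValueError(f"bands must cover scores {SCORE_MIN}..{SCORE_MAX}")
    for (lo, hi, _), nxt in zip(ordered, ordered[1:]):
        if hi < lo or nxt[0] != hi + 1:
            raise ValueError("bands must be contiguous and non-overlapping")
    if ordered[-1][1] < ordered[-1][0]:
        raise ValueError("bands must be contiguous and non-overlapping")


def map_to_birads(
    score: int,
    bands: Sequence[tuple[int, int, str]] = DEFAULT_BIRADS_BANDS,
) -> str:
    """Map a Kaiser score into a BI-RADS category band.

    ``bands`` is a sequence of ``(low, high, category)`` covering 1..12
    contiguously without overlap; the shipped default is a pragmatic,
    non-normative choice (1 -> 2, 2-4 -> 3, 5-7 -> 4, 8-12 -> 5).
    """
    _validate_bands(bands)
    for lo, hi, category in bands:
        if lo <= score <= hi:
            return category
    raise ValueError(f"score {score} not covered by the mapping")


def score_lesion(
    features: LesionFeatures,
    tree: DecisionTree,
    *,
    biopsy_threshold: int = DEFAULT_BIOPSY_THRESHOLD,
    birads_bands: Sequence[tuple[int, int, str]] | None = DEFAULT_BIRADS_BANDS,
) -> KaiserScore:
    """Score one lesion through ``tree`` and attach the management call.

    Deterministic: the complete descriptor vector reaches exactly one leaf.
    """
    value = tree.score(features)
    category = map_to_birads(value, birads_bands) if birads_bands else None
    return KaiserScore(
        value=value,
        biopsy_recommended=recommend_biopsy(value, biopsy_threshold),
        birads_category=category,
    )


def adapt_tree_for_cem(tree: DecisionTree) -> DecisionTree:
    """Derive the CEM variant of an MRI flowchart.

    Topology and leaf scores are unchanged — the adaptation narrows the
    *reading* of the oedema descriptor to diffuse ipsilateral breast
    oedema (CEM cannot depict perifocal oedema), it does not alter how a
    given descriptor vector is scored.
    """
    return dataclasses.replace(
        tree, variant="cem", oedema_criterion=CEM_OEDEMA_CRITERION
    )
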
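"""Class balancing by rotate/flip augmentation and the train/test split.

The diabetic-retinopathy grade distribution of screening datasets is heavily
skewed toward grade 0, so the minority DR grades are expanded to per-grade
target counts using the 8 lossless symmetries of the square raster (the
dihedral group D4: identity, rotations by 90/180/270 degrees, horizontal and
vertical flips, and the two flip-then-rotate compositions).  Each source
image contributes its identity variant; extra variants are dealt round-robin
over the sources in a seeded shuffled order, so per-source load is maximally
even and totals hit the targets exactly.

Splitting is seeded per-grade sampling without replacement.  The default is
leakage-safe: all variants of one source photograph land on the same side of
the split.  ``leakage_safe=False`` samples variants independently instead,
replicating the augment-then-split order of protocols that balance the
classes before splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_manifest import ManifestRecord, REFERABLE_MIN_GRADE, validate_manifest


class AugOp(Enum):
    """The 8 dihedral symmetries of a square image."""

    IDENTITY = "identity"
    ROT90 = "rot90"
    ROT180 = "rot180"
    ROT270 = "rot270"
    FLIPH = "fliph"
    FLIPV = "flipv"
    FLIPH_ROT90 = "fliph_rot90"
    FLIPV_ROT90 = "flipv_rot90"

    def apply(self, img: np.ndarray) -> np.ndarray:
        """Apply to an H×W or H×W×C array; rotations need a square raster."""
        a = np.asarray(img)
        if self is not AugOp.IDENTITY and a.shape[0] != a.shape[1] and \
                self not in (AugOp.FLIPH, AugOp.FLIPV):
            a = center_crop_square(a)
        if self is AugOp.IDENTITY:
            return a.copy()
        if self is AugOp.ROT90:
            return np.rot90(a, 1).copy()
        if self is AugOp.ROT180:
            return np.rot90(a, 2).copy()
        if self is AugOp.ROT270:
            return np.rot90(a, 3).copy()
        if self is AugOp.FLIPH:
            return a[:, ::-1].copy()
        if self is AugOp.FLIPV:
            return a[::-1, :].copy()
        if self is AugOp.FLIPH_ROT90:
            return np.rot90(a[:, ::-1], 1).copy()
        if self is AugOp.FLIPV_ROT90:
            return np.rot90(a[::-1, :], 1).copy()
        raise AssertionError(self)


#: fixed cycle used for extra (non-identity) variants
EXTRA_OP_CYCLE = (
    AugOp.ROT90, AugOp.ROT180, AugOp.ROT270, AugOp.FLIPH,
    AugOp.FLIPV, AugOp.FLIPH_ROT90, AugOp.FLIPV_ROT90,
)


def center_crop_square(img: np.ndarray) -> np.ndarray:
    """Crop the central square of a non-square raster."""
    h, w = img.shape[:2]
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return img[top:top + s, left:left + s]


@dataclass(frozen=True)
class Assignment:
    source_id: str
    op: AugOp
    new_id: str


@dataclass
class AugmentPlan:
    per_grade_targets: dict[int, int]
    assignments: list[Assignment] = field(default_factory=list)


class InfeasibleAugmentation(ValueError):
    """Target exceeds the 8 variants available per source image."""


def filter_interpretable(manifest: list[ManifestRecord]) -> list[ManifestRecord]:
    """Keep only images flagged interpretable (quality is graded upstream)."""
    kept = [r for r in manifest if r.interpretable]
    if manifest and not kept:
        warnings.warn("no interpretable images in manifest", stacklevel=2)
    return kept


def binarize_referable(manifest: list[ManifestRecord]) -> list[tuple[str, int]]:
    """Per-image binary referable-DR label: 1 iff grade >= 2."""
    return [(r.id, int(r.grade >= REFERABLE_MIN_GRADE)) for r in manifest]


def plan_augmentation(manifest: list[ManifestRecord],
                      targets: dict[int, int], seed: int) -> AugmentPlan:
    """Plan per-grade expansion to exact target counts.

    Grades absent from ``targets`` are passed through untouched (identity
    only).  Within a grade, every source contributes its identity variant and
    the remaining ``target - n_sources`` variants are assigned round-robin
    over a seeded shuffle of the sources, walking the fixed op cycle, so
    per-source variant counts differ by at most one.
    """
    validate_manifest(manifest)
    rng = np.random.default_rng(seed)
    by_grade: dict[int, list[ManifestRecord]] = {}
    for r in manifest:
        by_grade.setdefault(r.grade, []).append(r)

    plan = AugmentPlan(per_grade_targets=dict(targets))
    for grade in sorted(by_grade):
        sources = by_grade[grade]
        target = targets.get(grade, len(sources))
        if target < len(sources):
            raise InfeasibleAugmentation(
                f"grade {grade}: target {target} below source count {len(sources)}")
        if target > 8 * len(sources):
            raise InfeasibleAugmentation(
                f"grade {grade}: target {target} exceeds 8 x {len(sources)} "
                f"= {8 * len(sources)} dihedral variants")
        for r in sources:
            plan.assignments.append(Assignment(r.id, AugOp.IDENTITY, r.id))
        order = [sources[i] for i in rng.permutation(len(sources))]
        extra = target - len(sources)
        per_source_extras: dict[str, int] = {r.id: 0 for r in sources}
        i = 0
        for _ in range(extra):
            src = order[i % len(order)]
            k = per_source_extras[src.id]
            op = EXTRA_OP_CYCLE[k]
            per_source_extras[src.id] = k + 1
            plan.assignments.append(
                Assignment(src.id, op, f"{src.id}__{op.value}"))
            i += 1
    return plan


def apply_augmentation(plan: AugmentPlan,
                       store: dict[str, np.ndarray],
                       manifest: list[ManifestRecord],
                       ) -> tuple[dict[str, np.ndarray], list[ManifestRecord]]:
    """Materialise a plan against an in-memory image store.

    Returns the augmented store and manifest; new records inherit the grade
    of their source and carry its id as provenance.
    """
    by_id = {r.id: r for r in manifest}
    out_store: dict[str, np.ndarray] = {}
    out_manifest: list[ManifestRecord] = []
    for a in plan.assignments:
        if a.source_id not in store:
            raise KeyError(f"source image {a.source_id!r} missing from store")
        src = by_id[a.source_id]
        out_store[a.new_id] = a.op.apply(store[a.source_id])
        out_manifest.append(ManifestRecord(
            id=a.new_id, grade=src.grade, path=src.path,
            interpretable=src.interpretable, source_id=a.source_id))
    validate_manifest(out_manifest)
    return out_store, out_manifest


@dataclass(frozen=True)
class SplitSpec:
    train_per_grade: dict[int, int]
    test_per_grade: dict[int, int]
    seed: int
    leakage_safe: bool = True


class SplitError(ValueError):
    """Per-grade availability below train+test demand."""


def split_train_test(manifest: list[ManifestRecord], spec: SplitSpec,
                     ) -> tuple[list[ManifestRecord], list[ManifestRecord]]:
    """Seeded per-grade split into disjoint train and test manifests.

    Leakage-safe mode (default) samples whole source groups, so no augmented
    variant of a test photograph appears in training; group sampling stops
    once the grade's train demand is covered, and the per-grade train count
    is then trimmed to the exact demand (test takes the remainder).  With
    ``leakage_safe=False`` variants are sampled independently, replicating
    the augment-before-split order of screening pipelines that balance the
    classes first.
    """
    rng = np.random.default_rng(spec.seed)
    by_grade: dict[int, list[ManifestRecord]] = {}
    for r in manifest:
        by_grade.setdefault(r.grade, []).append(r)

    train: list[ManifestRecord] = []
    test: list[ManifestRecord] = []
    grades = sorted(set(spec.train_per_grade) | set(spec.test_per_grade))
    for grade in grades:
        want_train = spec.train_per_grade.get(grade, 0)
        want_test = spec.test_per_grade.get(grade, 0)
        pool = sorted(by_grade.get(grade, []), key=lambda r: r.id)
        if len(pool) < want_train + want_test:
            raise SplitError(
                f"grade {grade}: have {len(pool)}, need {want_train + want_test} "
                f"(short by {want_train + want_test - len(pool)})")
        if spec.leakage_safe:
            groups: dict[str, list[ManifestRecord]] = {}
            for r in pool:
                groups.setdefault(r.source_id, []).append(r)
            keys = sorted(groups)
            order = [keys[i] for i in rng.permutation(len(keys))]
            tr: list[ManifestRecord] = []
            rest: list[ManifestRecord] = []
            for k in order:
                (tr if len(tr) < want_train else rest).extend(groups[k])
            if len(tr) < want_train or len(rest) < want_test:
                raise SplitError(
                    f"grade {grade}: leakage-safe grouping cannot satisfy "
                    f"{want_train}/{want_test} from {len(pool)} variants")
            # overshoot from group granularity is dropped, never moved to
            # test, so no test source ever has a variant in train
            train.extend(tr[:want_train])
            pick = rng.permutation(len(rest))[:want_test]
            test.extend(rest[i] for i in sorted(pick))
        else:
            order = rng.permutation(len(pool))
            train.extend(pool[i] for i in order[:want_train])
            test.extend(pool[i] for i in order[want_train:want_train + want_test])
    return train, test
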
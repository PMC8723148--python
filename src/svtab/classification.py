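"""User-defined SV classification and per-sample feature matrices.

A :class:`ClassDefinition` is an ordered list of (class name, predicate)
rules. Predicates reuse the condition grammar of :mod:`svtab.filtering`
(conjunctions of ``"item op value"`` strings) and may OR several
conjunctions together, e.g. *either* breakend annotated as a fragile site.
Evaluation is first-match-wins and every record receives exactly one
class; records matching no rule get the fallback class. Because any INFO
key is a valid predicate item, arbitrary annotations (fragile sites,
replication timing, microhomology, copy number) can drive the classes.

Class labels are stored as a new INFO table (``manual_sv_type``), so they
survive VCF/BEDPE export and re-import. Counting labels across a
collection of samples yields the samples x classes
:class:`FeatureMatrix` consumed by signature extraction.

Two stock schemes are provided: ``simple`` (traditional SV types by five
length bins, 16 classes) and ``pcawg_like`` (25 classes over fragile-site
membership, replication timing and length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import IntervalIndex, annotate_bed
from .datamodel import MultiSVContainer, SVContainer, SVTabError
from .filtering import matching_ids

__all__ = [
    "ClassDefinition",
    "FeatureMatrix",
    "classify",
    "feature_matrix",
    "get_default_definitions",
]


def _as_dnf(predicate) -> list:
    """Normalize a predicate to a list of conjunctions (OR of ANDs)."""
    if isinstance(predicate, str):
        return [[predicate]]
    if predicate and all(isinstance(p, str) for p in predicate):
        return [list(predicate)]
    return [list(conj) for conj in predicate]


@dataclass
class ClassDefinition:
    """Ordered first-match-wins SV classification rules.

    ``rules`` is a list of ``(class_name, predicate)`` where predicate is a
    conjunction (list of condition strings) or a disjunction of
    conjunctions (list of lists). ``preparers`` are idempotent callables
    ``container -> container`` run before evaluation to add any INFO the
    predicates need (annotation, derived keys).
    """

    rules: list
    fallback_name: str = "others"
    preparers: list = field(default_factory=list)

    def __post_init__(self):
        names = [name for name, _ in self.rules]
        if len(names) != len(set(names)):
            raise SVTabError("class names must be unique")
        self.rules = [(name, _as_dnf(pred)) for name, pred in self.rules]

    @property
    def class_names(self) -> list:
        names = [name for name, _ in self.rules]
        if self.fallback_name not in names:
            names.append(self.fallback_name)
        return names


def classify(container: SVContainer, definition: ClassDefinition) -> SVContainer:
    """Label every record with its first matching class.

    Returns a new container with the INFO table ``manual_sv_type``
    (exactly one label per record; unmatched records get the fallback
    class). A predicate referencing an INFO key that is absent even after
    the definition's preparers have run raises an error naming the key.
    """
    for prep in definition.preparers:
        container = prep(container)
    labels = {rid: definition.fallback_name for rid in container.positions["id"]}
    unassigned = set(labels)
    for name, dnf in definition.rules:
        matched: set = set()
        for conj in dnf:
            ids = set(container.positions["id"])
            for cond in conj:
                try:
                    ids &= matching_ids(container, cond)
                except SVTabError as exc:
                    raise SVTabError(
                        f"class {name!r}: {exc} (annotate the container first?)"
                    ) from exc
            matched |= ids
        for rid in matched & unassigned:
            labels[rid] = name
        unassigned -= matched
    return container.add_info(
        "manual_sv_type",
        labels,
        number="1",
        type_="String",
        description="User-defined SV class",
        overwrite=True,
    )


@dataclass
class FeatureMatrix:
    """Samples x SV-class count matrix plus orderings.

    ``values`` is an integer DataFrame indexed by sample with one column
    per class; row sums equal each sample's classified record count.
    """

    values: pd.DataFrame
    sample_order: list
    class_order: list

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise SVTabError("feature matrix entries must be non-negative")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df, list(df.index), list(df.columns))


def feature_matrix(multi: MultiSVContainer, definition: ClassDefinition) -> FeatureMatrix:
    """Classify every member and count labels into a FeatureMatrix.

    Column order is rule order plus the fallback class; classes absent
    from a sample count 0.
    """
    if isinstance(multi, dict):
        multi = MultiSVContainer(multi)
    if len(multi) == 0:
        raise SVTabError("feature_matrix needs a non-empty collection of samples")
    classes = definition.class_names
    rows = {}
    for label, container in multi:
        classified = classify(container, definition)
        counts = classified.get_info("manual_sv_type")["value"].value_counts()
        rows[label] = [int(counts.get(c, 0)) for c in classes]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=classes).astype(int)
    return FeatureMatrix(values=values, sample_order=list(values.index), class_order=classes)


# --------------------------------------------------------------------------- #
# stock schemes
# --------------------------------------------------------------------------- #

_SIMPLE_BINS = [
    ("<1kb", ["svlen < 1000"]),
    ("1kb-10kb", ["svlen >= 1000", "svlen < 10000"]),
    ("10kb-100kb", ["svlen >= 10000", "svlen < 100000"]),
    ("100kb-1Mb", ["svlen >= 100000", "svlen < 1000000"]),
    (">1Mb", ["svlen >= 1000000"]),
]

_PCAWG_BINS = [
    ("small", ["svlen < 50000"]),
    ("medium", ["svlen >= 50000", "svlen < 500000"]),
    ("large", ["svlen >= 500000"]),
]


def _derive_timing_class(container: SVContainer) -> SVContainer:
    """Collapse the bp1 replication-timing annotation to one label.

    ``timingclass1`` is 'early' or 'late' when the bp1 annotation is
    unambiguous, and 'unknown' when the breakend has no timing annotation
    or overlaps zones of both kinds.
    """
    if "timingclass1" in container.infos:
        return container
    timing = container.info_dict("timing1")
    labels = {}
    for rid in container.positions["id"]:
        vals = {str(v).lower() for v in timing.get(rid, [])}
        vals &= {"early", "late"}
        labels[rid] = vals.pop() if len(vals) == 1 else "unknown"
    return container.add_info(
        "timingclass1", labels, number="1", type_="String",
        description="Replication-timing class of breakend 1",
    )


def get_default_definitions(
    scheme: str,
    cfs_index: IntervalIndex | None = None,
    timing_index: IntervalIndex | None = None,
) -> ClassDefinition:
    """Return one of the stock classification schemes.

    ``simple`` — 16 classes: {DEL, DUP, INV} x five length bins (<1 kb,
    1-10 kb, 10-100 kb, 100 kb-1 Mb, >1 Mb) plus ``translocation`` as the
    fallback for everything without an intrachromosomal length.

    ``pcawg_like`` — 25 classes over three axes: fragile-site membership
    (either breakend; 1 class, highest priority), then {DEL, DUP, INV} x
    {early, late} replication timing x {<50 kb, 50-500 kb, >500 kb}
    (18 classes), {DEL, DUP, INV} with unknown timing (3), translocation,
    insertion, and the ``others`` fallback. Requires interval indexes for
    fragile sites and replication timing (timing BED names must read
    'early'/'late'); both are applied automatically when the container
    lacks the annotations.
    """
    if scheme == "simple":
        rules = []
        for svtype in ("DEL", "DUP", "INV"):
            for bin_name, conds in _SIMPLE_BINS:
                rules.append((f"{svtype}_{bin_name}", [f"svtype == {svtype}"] + conds))
        return ClassDefinition(rules=rules, fallback_name="translocation")

    if scheme == "pcawg_like":
        if cfs_index is None or timing_index is None:
            raise SVTabError(
                "pcawg_like needs both a fragile-site and a replication-timing index"
            )

        def prepare(container: SVContainer) -> SVContainer:
            if "cfs1" not in container.infos:
                container = annotate_bed(container, cfs_index, "cfs", mode="presence")
            if "timing1" not in container.infos:
                container = annotate_bed(container, timing_index, "timing", mode="value")
            return _derive_timing_class(container)

        rules = [("CFS_SV", [["cfs1 == True"], ["cfs2 == True"]])]
        for svtype in ("DEL", "DUP", "INV"):
            for timing in ("early", "late"):
                for bin_name, conds in _PCAWG_BINS:
                    rules.append(
                        (
                            f"{svtype}_{timing}_{bin_name}",
                            [f"svtype == {svtype}", f"timingclass1 == {timing}"] + conds,
                        )
                    )
        for svtype in ("DEL", "DUP", "INV"):
            rules.append(
                (f"{svtype}_unknown_timing",
                 [f"svtype == {svtype}", "timingclass1 == unknown"])
            )
        rules.append(("translocation", ["svtype == BND"]))
        rules.append(("insertion", ["svtype == INS"]))
        return ClassDefinition(rules=rules, fallback_name="others", preparers=[prepare])

    raise SVTabError(f"unknown scheme {scheme!r}; use 'simple' or 'pcawg_like'")
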
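"""AFQ-Browser-dialect tract-profile I/O and grouped feature assembly.

Tract profiles arrive as a ``nodes.csv`` (one row per subject x bundle x
node, metric columns wide) plus a ``subjects.csv`` (one row per subject,
phenotype columns).  Internally profiles are held long — one row per
(subject, bundle, metric, node) — and assembled into an S x P design matrix
whose columns carry an explicit partition into G = B x M groups, one group
per (bundle, metric) pair, nodes ordered within each group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, IntegrityError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BUNDLES",
    "TractProfileTable",
    "PhenotypeTarget",
    "GroupedFeatureMatrix",
    "read_afq_csv",
    "write_afq_csv",
    "assemble_feature_matrix",
    "export_coefficient_profiles",
]

#: The 18 major bundles of the default AFQ segmentation.
DEFAULT_BUNDLES = (
    "CSTR", "CSTL", "UNCR", "UNCL", "IFOL", "IFOR", "ARCR", "ARCL",
    "ATRR", "ATRL", "CGCR", "CGCL", "CFP", "CFA", "ILFR", "ILFL",
    "SLFR", "SLFL",
)

_NODE_COLS = ("subjectID", "tractID", "nodeID")


@dataclass
class TractProfileTable:
    """Long-format tract profiles: one row per subject/bundle/metric/node.

    ``data`` has columns subjectID, tractID, metric, nodeID, value; missing
    node values are NaN.  ``n_nodes`` is the (single) profile length N.
    """

    data: pd.DataFrame
    n_nodes: int

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        key = ["subjectID", "tractID", "metric", "nodeID"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise IntegrityError(
                "duplicate profile row for subject "
                f"{dup['subjectID']!r}, tract {dup['tractID']!r}, "
                f"metric {dup['metric']!r}, node {dup['nodeID']}"
            )
        if len(df) and (
            df["nodeID"].min() < 0 or df["nodeID"].max() >= self.n_nodes
        ):
            raise IntegrityError(
                f"node indices must lie in [0, {self.n_nodes})"
            )
        fa = df[df["metric"] == "FA"]["value"].dropna()
        if len(fa) and (fa.min() < 0 or fa.max() > 1):
            raise IntegrityError("FA values must lie in [0, 1]")

    @property
    def subjects(self) -> list:
        return sorted(self.data["subjectID"].unique())

    @property
    def bundles(self) -> list:
        return sorted(self.data["tractID"].unique())

    @property
    def metrics(self) -> list:
        return sorted(self.data["metric"].unique())


@dataclass
class PhenotypeTarget:
    """Per-subject target values in canonical (sorted subjectID) order."""

    values: np.ndarray
    kind: str  # "continuous" | "binary"
    transform: str = "identity"  # "identity" | "log"
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.kind == "binary":
            classes = np.unique(self.values)
            if not np.array_equal(classes, [0.0, 1.0]):
                raise ValueError(
                    "binary target must contain exactly the classes {0, 1}, "
                    f"got {classes}"
                )


@dataclass
class GroupedFeatureMatrix:
    """S x P design matrix with an explicit column partition into groups.

    One group per (bundle, metric) pair; ``column_meta`` rows carry the
    (tractID, metric, nodeID) coordinate of each column, with node varying
    fastest within a group.
    """

    values: np.ndarray
    groups: list
    column_meta: pd.DataFrame  # columns tractID, metric, nodeID
    subject_ids: list
    group_labels: list  # (tractID, metric) per group

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        P = self.values.shape[1]
        idx = np.sort(np.concatenate([np.asarray(g) for g in self.groups]))
        if not np.array_equal(idx, np.arange(P)):
            raise DimensionError("groups must partition the feature columns")
        if len(self.column_meta) != P:
            raise DimensionError("column_meta length must equal P")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "GroupedFeatureMatrix":
        """Copy of this matrix with new values, same structure."""
        return GroupedFeatureMatrix(
            values=np.asarray(values, dtype=float),
            groups=self.groups,
            column_meta=self.column_meta,
            subject_ids=self.subject_ids,
            group_labels=self.group_labels,
        )

    def rows(self, index) -> "GroupedFeatureMatrix":
        """Row-subset copy (e.g. one CV fold)."""
        index = np.asarray(index)
        return GroupedFeatureMatrix(
            values=self.values[index],
            groups=self.groups,
            column_meta=self.column_meta,
            subject_ids=[self.subject_ids[i] for i in index],
            group_labels=self.group_labels,
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_afq_csv(
    nodes_path,
    subjects_path,
    target_column: str,
    metrics: list[str] | None = None,
    target_kind: str = "auto",
    target_transform: str = "identity",
    bundle_vocabulary: tuple = DEFAULT_BUNDLES,
) -> tuple[TractProfileTable, PhenotypeTarget]:
    """Read an AFQ-Browser nodes.csv / subjects.csv pair.

    Returns the profile table restricted to ``metrics`` (all metric columns
    when None) and the phenotype target in canonical sorted-subject order.
    Subjects with a missing target are dropped with a warning.  1-based node
    indices are detected (min node 1 while a 0 node never appears) and
    normalized to 0-based.
    """
    nodes = pd.read_csv(
        nodes_path, na_values=["NaN"], keep_default_na=True,
        float_precision="round_trip",
    )
    for col in _NODE_COLS:
        if col not in nodes.columns:
            raise FormatError(f"nodes file is missing required column {col!r}")
    metric_cols = [c for c in nodes.columns if c not in _NODE_COLS]
    if metrics is None:
        metrics = metric_cols
    else:
        missing = [m for m in metrics if m not in metric_cols]
        if missing:
            raise FormatError(
                f"nodes file is missing requested metric column(s) {missing}"
            )

    if nodes.duplicated(subset=list(_NODE_COLS)).any():
        dup = nodes[nodes.duplicated(subset=list(_NODE_COLS))].iloc[0]
        raise IntegrityError(
            f"duplicate row for subject {dup['subjectID']!r}, tract "
            f"{dup['tractID']!r}, node {dup['nodeID']}"
        )

    subjects = pd.read_csv(
        subjects_path, na_values=["NaN"], float_precision="round_trip"
    )
    if "subjectID" not in subjects.columns:
        raise FormatError("subjects file is missing required column 'subjectID'")
    if target_column not in subjects.columns:
        raise FormatError(
            f"subjects file is missing target column {target_column!r}"
        )
    known = set(subjects["subjectID"].astype(str))
    in_nodes = set(nodes["subjectID"].astype(str))
    orphans = sorted(in_nodes - known)
    if orphans:
        raise IntegrityError(
            f"subject(s) {orphans} appear in the nodes file but not in the "
            "subjects file"
        )

    unknown = sorted(set(nodes["tractID"]) - set(bundle_vocabulary))
    if unknown:
        logger.warning(
            "tract name(s) %s are not in the default bundle vocabulary; "
            "rows retained under their literal names", unknown
        )

    # 1-based node detection
    node_min, node_max = nodes["nodeID"].min(), nodes["nodeID"].max()
    if node_min == 1:
        logger.warning(
            "node indices appear 1-based (min node 1, max %d); "
            "normalizing to 0-based", node_max
        )
        nodes = nodes.assign(nodeID=nodes["nodeID"] - 1)
        node_max -= 1
    n_nodes = int(node_max) + 1

    # drop subjects with missing target
    tgt = subjects.set_index(subjects["subjectID"].astype(str))[target_column]
    dropped = sorted(s for s in in_nodes if pd.isna(tgt.get(s, np.nan)))
    if dropped:
        logger.warning(
            "dropping subject(s) %s with missing %r", dropped, target_column
        )
        nodes = nodes[~nodes["subjectID"].astype(str).isin(dropped)]

    long = nodes.melt(
        id_vars=list(_NODE_COLS),
        value_vars=list(metrics),
        var_name="metric",
        value_name="value",
    )
    long["subjectID"] = long["subjectID"].astype(str)
    table = TractProfileTable(
        data=long.reset_index(drop=True), n_nodes=n_nodes
    )

    order = sorted(set(long["subjectID"]))
    y = np.asarray([tgt.loc[s] for s in order], dtype=float)
    if target_kind == "auto":
        target_kind = (
            "binary" if np.isin(np.unique(y), (0.0, 1.0)).all() and
            len(np.unique(y)) == 2 else "continuous"
        )
    target = PhenotypeTarget(
        values=y,
        kind=target_kind,
        transform=target_transform,
        subject_ids=order,
    )
    return table, target


def write_afq_csv(
    table: TractProfileTable,
    target: PhenotypeTarget,
    nodes_path,
    subjects_path,
    target_column: str = "target",
) -> None:
    """Write the AFQ-Browser nodes.csv / subjects.csv pair."""
    wide = (
        table.data.pivot_table(
            index=list(_NODE_COLS),
            columns="metric",
            values="value",
            dropna=False,
        )
        .reset_index()
    )
    wide.columns.name = None
    # %.17g guarantees a bit-exact float round trip through the CSV
    wide.to_csv(nodes_path, index=False, float_format="%.17g")
    pd.DataFrame(
        {"subjectID": target.subject_ids, target_column: target.values}
    ).to_csv(subjects_path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_feature_matrix(table: TractProfileTable) -> GroupedFeatureMatrix:
    """Pivot the long profile table into the grouped S x P design matrix.

    Columns are ordered by (bundle, metric, node) with node fastest; one
    group per (bundle, metric); rows follow canonical sorted subject order.
    A subject lacking an entire (bundle, metric) combination is a structural
    error; individual missing node values become NaN.
    """
    df = table.data
    N = table.n_nodes
    subjects = sorted(df["subjectID"].unique())
    combos = sorted(
        set(zip(df["tractID"], df["metric"])), key=lambda bm: (bm[0], bm[1])
    )

    # structural check: every subject has every combination observed somewhere
    present = df.dropna(subset=["value"]).groupby(
        ["subjectID", "tractID", "metric"]
    ).size()
    missing_combos = [
        (s, bm)
        for s in subjects
        for bm in combos
        if (s, bm[0], bm[1]) not in present.index
    ]
    if missing_combos:
        s, bm = missing_combos[0]
        raise StructuralError(
            f"subject {s!r} has no observed values for bundle/metric "
            f"{bm}; {len(missing_combos)} such absences in total"
        )

    pivot = df.pivot_table(
        index="subjectID",
        columns=["tractID", "metric", "nodeID"],
        values="value",
        dropna=False,
    )
    full_cols = pd.MultiIndex.from_tuples(
        [(b, m, n) for b, m in combos for n in range(N)],
        names=["tractID", "metric", "nodeID"],
    )
    pivot = pivot.reindex(index=subjects, columns=full_cols)

    values = pivot.to_numpy(dtype=float)
    groups = [
        np.arange(i * N, (i + 1) * N, dtype=np.intp)
        for i in range(len(combos))
    ]
    meta = pd.DataFrame(
        [(b, m, n) for b, m in combos for n in range(N)],
        columns=["tractID", "metric", "nodeID"],
    )
    return GroupedFeatureMatrix(
        values=values,
        groups=groups,
        column_meta=meta,
        subject_ids=list(subjects),
        group_labels=list(combos),
    )


# ---------------------------------------------------------------------------
# Coefficient export
# ---------------------------------------------------------------------------

def export_coefficient_profiles(
    model, matrix: GroupedFeatureMatrix, out_path
) -> pd.DataFrame:
    """Write fitted coefficients back into (tractID, metric, nodeID) space.

    Emits ``out_path`` with columns tractID, metric, nodeID, coefficient and
    a sibling ``<out_path stem>_group_summary.csv`` with the mean absolute
    coefficient per bundle-metric group.  Accepts anything with a
    ``coefficients`` vector of length P (an SGL model, a PCR-SGL model with
    back-projected coefficients, or a bagged ensemble's mean coefficients).
    """
    import os

    beta = np.asarray(
        model.coefficients if hasattr(model, "coefficients") else model,
        dtype=float,
    )
    if beta.shape[0] != matrix.n_features:
        raise DimensionError(
            f"coefficient length {beta.shape[0]} != matrix P "
            f"{matrix.n_features}"
        )
    out = matrix.column_meta.copy()
    out["coefficient"] = beta
    out.to_csv(out_path, index=False)

    summary = (
        out.assign(abs_coef=np.abs(beta))
        .groupby(["tractID", "metric"], sort=True)["abs_coef"]
        .mean()
        .reset_index()
        .rename(columns={"abs_coef": "mean_abs_coefficient"})
    )
    stem, ext = os.path.splitext(str(out_path))
    summary.to_csv(f"{stem}_group_summary{ext or '.csv'}", index=False)
    return out
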
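"""Promoter divergence vs expression divergence between paralogs.

Promoter divergence between two paralogs is the Jaccard index of their TF
repertoires (the sets of distinct TF labels bound in their proximal
promoters); expression divergence is one minus their co-expression across
samples.  Pairs are enumerated within gene families, optionally reduced to
each gene's youngest pair (its most recent duplication) to avoid
pseudo-replication in large families, stratified by the taxon (age) of the
duplication node, and classified by the breadth classes of the two daughters
(housekeeping-conserved / tissue-specific-conserved / transformative).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import CorrelationResult, correlate
from .expression import BreadthClass

__all__ = [
    "DEFAULT_AGE_GROUPS",
    "EventClass",
    "ParalogPair",
    "TaxonGroupAssignment",
    "jaccard_repertoire",
    "enumerate_all_pairs",
    "select_youngest_pairs",
    "divergence_analysis",
    "build_divergence_records",
    "classify_event",
    "age_group_summary",
    "read_paralog_table",
]

# Youngest-first ordering; each duplication maps to the youngest matching group.
DEFAULT_AGE_GROUPS = ("Primate", "Mammalian", "Vertebrate", "Animal", "Eukaryotic")


class EventClass(str, enum.Enum):
    HOUSEKEEPING_CONSERVED = "housekeeping_conserved"
    TISSUE_SP_CONSERVED = "tissue_sp_conserved"
    TRANSFORMATIVE = "transformative"
    OTHER = "other"


@dataclass(frozen=True)
class ParalogPair:
    family: str
    node: str
    taxon: str
    gene_x: str
    gene_y: str
    family_side_x: int = 1
    family_side_y: int = 2

    def __post_init__(self) -> None:
        if self.gene_x == self.gene_y:
            raise ValueError("a pair must join two distinct genes")


@dataclass(frozen=True)
class TaxonGroupAssignment:
    """Ordered age groups (youngest first) and a taxon -> group map."""

    groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    taxon_to_group: Mapping[str, str] | None = None

    def group_of(self, taxon: str) -> str:
        if self.taxon_to_group is not None:
            return self.taxon_to_group[taxon]
        if taxon not in self.groups:
            raise KeyError(f"taxon {taxon!r} has no age group")
        return taxon

    def age_index(self, taxon: str) -> int:
        return self.groups.index(self.group_of(taxon))


def jaccard_repertoire(tf_set_x: Sequence[str] | set, tf_set_y: Sequence[str] | set) -> float:
    """|X n Y| / |X u Y| on sets of distinct TF labels (multiplicity ignored).

    1 when the intersection equals the (non-empty) union, 0 when disjoint;
    defined as 0 when both repertoires are empty.
    """
    x, y = set(tf_set_x), set(tf_set_y)
    union = x | y
    if not union:
        return 0.0
    return len(x & y) / len(union)


def enumerate_all_pairs(family_members: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) unordered pairs of family members (empty when n < 2)."""
    return list(itertools.combinations(family_members, 2))


def read_paralog_table(source) -> pd.DataFrame:
    """Read a tab-delimited pair table with the denormalized duplication-node
    fields: family, node, taxon, gene.x, gene.y, familySide.x, familySide.y."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"family", "node", "taxon", "gene.x", "gene.y", "familySide.x", "familySide.y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"paralog table missing columns: {sorted(missing)}")
    return df


def select_youngest_pairs(
    pairs: pd.DataFrame,
    assignment: TaxonGroupAssignment = TaxonGroupAssignment(),
) -> pd.DataFrame:
    """Each paralog's comparison through its most recent duplication node only.

    Input rows carry gene.x/gene.y, node, taxon and familySide flags; rows
    whose two genes sit on the same side of their node are invalid
    comparisons and dropped.  For every gene the pair through its youngest
    node is retained (ties broken by partner id, at most one pair per gene
    and node), and the retained pairs are deduplicated.
    """
    try:
        ages = pairs["taxon"].map(lambda t: assignment.age_index(t))
    except KeyError as exc:
        raise ValueError(f"missing age for taxon: {exc}") from None
    valid = pairs.loc[pairs["familySide.x"] != pairs["familySide.y"]].copy()
    valid["_age"] = ages[valid.index]

    # long form: one entry per (gene, pair) in either orientation, so a
    # gene's candidates cover pairs where it appears as gene.x or gene.y
    long = pd.concat(
        [
            valid[["family", "gene.x", "gene.y", "_age"]].rename(
                columns={"gene.x": "gene", "gene.y": "partner"}
            ),
            valid[["family", "gene.y", "gene.x", "_age"]].rename(
                columns={"gene.y": "gene", "gene.x": "partner"}
            ),
        ]
    )
    keep: set[int] = set()
    for _, grp in long.groupby(["family", "gene"], sort=False):
        youngest = grp["_age"].min()
        cand = grp.loc[grp["_age"] == youngest]
        keep.add(cand.sort_values("partner").index[0])
    out = valid.loc[sorted(keep)].drop(columns="_age")
    return out.reset_index(drop=True)


def classify_event(
    breadth_class_x: BreadthClass | str, breadth_class_y: BreadthClass | str
) -> EventClass:
    """Duplication-event class from the daughters' breadth classes.

    Both housekeeping -> housekeeping-conserved; both narrow ->
    tissue-specific-conserved; one narrow + one housekeeping ->
    transformative; any combination involving intermediate or unexpressed
    daughters -> other.
    """
    bx = BreadthClass(breadth_class_x)
    by = BreadthClass(breadth_class_y)
    if bx == by == BreadthClass.HOUSEKEEPING:
        return EventClass.HOUSEKEEPING_CONSERVED
    if bx == by == BreadthClass.NARROW:
        return EventClass.TISSUE_SP_CONSERVED
    if {bx, by} == {BreadthClass.NARROW, BreadthClass.HOUSEKEEPING}:
        return EventClass.TRANSFORMATIVE
    return EventClass.OTHER


def divergence_analysis(
    records: pd.DataFrame,
    breadth_stratum: str | tuple[str, str] | None = None,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of promoter divergence (JI) with co-expression.

    ``records`` needs 'ji' and 'coexpr' columns (plus breadth_class_x/y when
    a stratum is requested).  ``breadth_stratum`` restricts to pairs where
    both daughters share the named class, or to the unordered class pair
    given as a tuple (e.g. ('narrow', 'housekeeping')).
    """
    df = records
    if breadth_stratum is not None:
        if isinstance(breadth_stratum, str):
            want = {breadth_stratum}
        else:
            want = set(breadth_stratum)
        mask = [
            {BreadthClass(a).value, BreadthClass(b).value} == {BreadthClass(w).value for w in want}
            for a, b in zip(df["breadth_class_x"], df["breadth_class_y"])
        ]
        df = df.loc[mask]
    if len(df) < 3:
        raise ValueError("fewer than 3 records in the requested stratum")
    return correlate(df["ji"], df["coexpr"], method=method)


def build_divergence_records(
    pairs: pd.DataFrame,
    repertoires: Mapping[str, frozenset | set],
    expression: pd.DataFrame,
    on_cutoff: float = 10.0,
    coexpr_method: str = "pearson",
) -> pd.DataFrame:
    """Per-pair divergence table: JI, co-expression, breadth and event classes.

    ``pairs`` carries gene.x/gene.y/node/taxon columns; repertoires map genes
    to TF label sets; ``expression`` is a gene x sample TPM frame.  The
    returned records also carry per-pair mean BoE and mean repertoire size,
    ready for :func:`divergence_analysis` and :func:`age_group_summary`.
    """
    from .expression import breadth, classify_breadth

    boe = {g: breadth(expression.loc[g].to_numpy(), on_cutoff) for g in expression.index}
    rows = []
    for _, rec in pairs.iterrows():
        gx, gy = rec["gene.x"], rec["gene.y"]
        x = expression.loc[gx].to_numpy()
        y = expression.loc[gy].to_numpy()
        co = correlate(x, y, method=coexpr_method)
        cx = classify_breadth(boe[gx])
        cy = classify_breadth(boe[gy])
        rows.append({
            "family": rec["family"],
            "node": rec["node"],
            "taxon": rec["taxon"],
            "gene_x": gx,
            "gene_y": gy,
            "ji": jaccard_repertoire(repertoires[gx], repertoires[gy]),
            "coexpr": 0.0 if co.constant_input else co.r,
            "breadth_class_x": cx.value,
            "breadth_class_y": cy.value,
            "event_class": classify_event(cx, cy).value,
            "boe": 0.5 * (boe[gx] + boe[gy]),
            "tfbs_no": 0.5 * (len(repertoires[gx]) + len(repertoires[gy])),
        })
    return pd.DataFrame(rows)


def age_group_summary(
    records: pd.DataFrame,
    assignment: TaxonGroupAssignment = TaxonGroupAssignment(),
    boe_col: str = "boe",
    tfbs_col: str = "tfbs_no",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-age-group means of BoE and TfbsNo plus all pairwise Wilcoxon tests.

    Returns ``(summary, tests)``: the summary has one row per group (ordered
    youngest first) with mean/sd/n of both variables; the tests table holds
    every pairwise Wilcoxon rank-sum comparison for each variable with
    Holm-adjusted p-values.  Groups with n < 2 are excluded from testing and
    flagged in the summary.
    """
    df = records.copy()
    df["_group"] = df["taxon"].map(assignment.group_of)
    order = [g for g in assignment.groups if g in set(df["_group"])]

    rows = []
    for g in order:
        sub = df.loc[df["_group"] == g]
        rows.append(
            {
                "group": g,
                "mean_boe": float(sub[boe_col].mean()),
                "sd_boe": float(sub[boe_col].std(ddof=1)) if len(sub) > 1 else float("nan"),
                "mean_tfbs": float(sub[tfbs_col].mean()),
                "sd_tfbs": float(sub[tfbs_col].std(ddof=1)) if len(sub) > 1 else float("nan"),
                "n": int(len(sub)),
                "tested": len(sub) >= 2,
            }
        )
    summary = pd.DataFrame(rows).set_index("group")

    testable = [g for g in order if summary.loc[g, "tested"]]
    test_rows = []
    for var in (boe_col, tfbs_col):
        raw = []
        combos = list(itertools.combinations(testable, 2))
        for a, b in combos:
            xa = df.loc[df["_group"] == a, var]
            xb = df.loc[df["_group"] == b, var]
            stat, p = stats.ranksums(xa, xb)
            raw.append((a, b, float(stat), float(p)))
        if raw:
            adj = multipletests([r[3] for r in raw], method="holm")[1]
            for (a, b, stat, p), p_adj in zip(raw, adj):
                test_rows.append(
                    {"variable": var, "group_a": a, "group_b": b, "statistic": stat, "p_raw": p, "p_holm": float(p_adj)}
                )
    tests = pd.DataFrame(test_rows, columns=["variable", "group_a", "group_b", "statistic", "p_raw", "p_holm"])
    return summary, tests
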
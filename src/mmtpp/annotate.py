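"""Membrane classification, EASE-score enrichment, and binder summaries.

Classification follows the GO-plus-topology route used for membrane
proteomics libraries: proteins carrying a membrane GO annotation are split
by their predicted transmembrane-segment (TMS) count into integral membrane
proteins (>= 1 TMS) and membrane-associated proteins (0 TMS); everything
else is soluble.  TMS counts are external predictions consumed as
annotation — no topology prediction happens here.

Enrichment uses the conservative EASE score (DAVID's "jackknife" Fisher
exact test): the one-tailed hypergeometric upper tail computed after
removing one protein from the query-term overlap, so single-protein
overlaps can never appear significant.  Multiple testing is handled with
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from mmtpp.errors import ValidationError
from mmtpp.tables_io import AnnotationTable

__all__ = [
    "MEMBRANE_GO_TERMS",
    "classify_membrane",
    "classify_proteins",
    "ease_score",
    "bh_adjust",
    "enrich_terms",
    "group_redundant_terms",
    "binder_fraction_summary",
]

LABEL_IMP = "IMP"
LABEL_MEMBRANE_ASSOCIATED = "membrane_associated"
LABEL_SOLUBLE = "soluble"

#: GO identifiers/labels accepted as "membrane"; annotation tables are
#: expected pre-expanded (descendants already mapped to these), no ontology
#: traversal happens in-package.
MEMBRANE_GO_TERMS = frozenset({"GO:0016020", "membrane"})


def classify_membrane(
    go_terms: set[str] | None,
    tms_count: int | None,
    membrane_terms: frozenset[str] = MEMBRANE_GO_TERMS,
) -> str:
    """Classify one protein as IMP / membrane_associated / soluble.

    Only proteins with a membrane GO term are routed to the TMS rule, so a
    TMS count is required for them; proteins without the membrane term are
    soluble regardless of topology.  ``go_terms=None`` (no annotation at
    all) is treated as soluble with a warning.
    """
    if go_terms is None:
        warnings.warn("protein without annotation classified as soluble")
        return LABEL_SOLUBLE
    if membrane_terms & set(go_terms):
        if tms_count is None:
            raise ValidationError(
                "membrane-annotated protein lacks a TMS count; "
                "TMS prediction is required for GO-membrane proteins"
            )
        return LABEL_IMP if tms_count >= 1 else LABEL_MEMBRANE_ASSOCIATED
    return LABEL_SOLUBLE


def classify_proteins(
    protein_ids: list[str], annotations: AnnotationTable
) -> pd.DataFrame:
    """Classification table (protein_id, class) for a protein list."""
    labels = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one summary instead of one per protein
        for pid in protein_ids:
            ann = annotations.get(pid)
            if ann is None:
                labels.append(LABEL_SOLUBLE)
            else:
                labels.append(classify_membrane(ann.go_terms, ann.tms_count))
    return pd.DataFrame({"protein_id": protein_ids, "class": labels})


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValidationError(
            f"inconsistent 2x2 margins: k={k}, n={n}, K={K}, N={N}"
        )


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """Conservative one-tailed Fisher p for term enrichment (EASE score).

    k overlapping proteins between a query of size n and a term with K
    background members, background size N.  The query-term overlap is
    decremented by one before taking the hypergeometric upper tail, which
    shrinks every margin it contributes to by one; overlaps of 0 or 1
    therefore always score 1.0.
    """
    _check_margins(k, n, K, N)
    if k <= 1:
        return 1.0
    # decremented table: overlap k-1, margins n-1, K-1, total N-1
    return float(hypergeom.sf(k - 2, N - 1, K - 1, n - 1))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(~np.isfinite(pvals)) or np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def enrich_terms(
    query: set[str],
    background: set[str],
    annotations: AnnotationTable,
    namespace: str = "go",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """EASE enrichment of annotation terms in a query set vs a background.

    Returns one row per term with >= 1 query member, sorted by (bh_q,
    ease_p, term), with columns term, k, n, K, N, ease_p, bh_q and a
    ``significant`` flag requiring both ease_p < alpha and bh_q < alpha.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValidationError("query must be a subset of the background")
    if not background:
        raise ValidationError("empty background")
    term_members: dict[str, set[str]] = {}
    for pid in background:
        for term in annotations.terms_of(pid, namespace):
            term_members.setdefault(term, set()).add(pid)
    N, n = len(background), len(query)
    rows = []
    for term, members in term_members.items():
        k = len(members & query)
        if k < 1:
            continue
        rows.append((term, k, n, len(members), N, ease_score(k, n, len(members), N)))
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "ease_p", "bh_q", "significant"]
        )
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "ease_p"])
    out["bh_q"] = bh_adjust(out["ease_p"].to_numpy())
    out["significant"] = (out["ease_p"] < alpha) & (out["bh_q"] < alpha)
    return out.sort_values(
        ["bh_q", "ease_p", "term"], kind="stable"
    ).reset_index(drop=True)


def group_redundant_terms(
    results: pd.DataFrame,
    query: set[str],
    annotations: AnnotationTable,
    namespace: str = "go",
) -> pd.DataFrame:
    """Collapse terms whose query hits are the identical protein set.

    A lightweight redundancy reduction: terms backed by exactly the same
    query proteins are grouped; the best-scoring term represents the group
    and the others are listed in ``grouped_with``.
    """
    if results.empty:
        out = results.copy()
        out["grouped_with"] = pd.Series(dtype=str)
        return out
    hit_sets = {}
    for term in results["term"]:
        members = {p for p in query if term in annotations.terms_of(p, namespace)}
        hit_sets[term] = frozenset(members)
    groups: dict[frozenset, list[str]] = {}
    for term in results["term"]:  # results already sorted best-first
        groups.setdefault(hit_sets[term], []).append(term)
    keep_rows = []
    for _, row in results.iterrows():
        members = groups[hit_sets[row["term"]]]
        if members[0] == row["term"]:
            row = row.copy()
            row["grouped_with"] = ";".join(members[1:])
            keep_rows.append(row)
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def binder_fraction_summary(
    results: pd.DataFrame,
    annotations: AnnotationTable,
    tag: str,
) -> pd.DataFrame:
    """Percentage of tag-annotated proteins among all vs shifted proteins.

    For each temperature and pooled over all temperatures ("overall"),
    reports the percentage of proteins carrying *tag* among every retained
    protein (``pct_all``) and among proteins called stabilized or
    destabilized (``pct_shifted``).  A set with no members yields 0.
    """
    required = {"protein_id", "temperature_C", "call"}
    if not required <= set(results.columns):
        raise ValidationError(f"results table needs columns {sorted(required)}")
    tagged = annotations.proteins_with_tag(tag)

    def pct(proteins: set[str]) -> float:
        if not proteins:
            return 0.0
        return 100.0 * len(proteins & tagged) / len(proteins)

    rows = []
    for t in sorted(results["temperature_C"].unique()):
        sub = results[results["temperature_C"] == t]
        all_ids = set(sub["protein_id"])
        shifted = set(sub.loc[sub["call"] != "unchanged", "protein_id"])
        rows.append((f"{t:g}", len(all_ids), len(shifted), pct(all_ids), pct(shifted)))
    all_ids = set(results["protein_id"])
    shifted = set(results.loc[results["call"] != "unchanged", "protein_id"])
    rows.append(("overall", len(all_ids), len(shifted), pct(all_ids), pct(shifted)))
    return pd.DataFrame(
        rows, columns=["temperature_C", "n_all", "n_shifted", "pct_all", "pct_shifted"]
    )
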
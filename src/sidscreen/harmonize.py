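"""Join ICD-9 and ICD-10 cause-of-death codes into harmonized groups.

U.S. mortality files switched from ICD-9 to ICD-10 coding in 1999, and the
official General Equivalence Mappings (GEM) between the two revisions are
many-to-many.  To analyze a cause across the transition, the observed codes of
both revisions are treated as nodes of an undirected graph with an edge
wherever a GEM row (in either direction) links two observed codes; each
connected component of that graph becomes one harmonized "joined" cause group.

Only codes actually observed in the cohort enter the graph: using the full GEM
universe would merge groups through bridge codes that never occur in the data.
GEM flag fields (approximate / no-map / combination) are kept but ignored for
edge construction by default — any listed pair counts as an equivalence; an
``edge_filter`` predicate on the flag string is available for sensitivity
analyses.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "GemEntry",
    "JoinedCode",
    "normalize_code",
    "parse_gem_file",
    "build_code_graph",
    "connected_components",
    "assign_joined_codes",
    "CodeHarmonizer",
    "write_component_table",
]

Node = tuple[str, int]  # (normalized code, icd version)


def normalize_code(code: str) -> str:
    """Normalize an ICD code: uppercase, strip periods and surrounding space."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class GemEntry:
    """One GEM crosswalk row.

    ``direction`` is ``"forward"`` for ICD-10-CM→ICD-9-CM files and
    ``"backward"`` for ICD-9-CM→ICD-10-CM; it fixes which revision each code
    column belongs to.  ``flags`` is the GEM attribute string, retained as
    opaque text.
    """

    source: str
    target: str
    direction: str  # "forward" (10 -> 9) or "backward" (9 -> 10)
    flags: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown GEM direction {self.direction!r}")
        if not self.source or not self.target:
            raise ValueError("GEM entry codes must be non-empty")

    @property
    def nodes(self) -> tuple[Node, Node]:
        """The (code, version) endpoints this entry links."""
        if self.direction == "forward":
            return (self.source, 10), (self.target, 9)
        return (self.source, 9), (self.target, 10)


@dataclass(frozen=True)
class JoinedCode:
    """A harmonized cause group: one connected component of the code graph.

    ``id`` is the lexicographically smallest member code — deterministic and
    stable across runs; human-readable aliases live outside the algorithm.
    """

    id: str
    members: frozenset[Node]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("JoinedCode needs at least one member")


def parse_gem_file(stream, direction: str) -> list[GemEntry]:
    """Parse a whitespace-separated GEM text file into entries.

    Lines hold ``source_code target_code [flags]``; blank lines and lines
    starting with ``#`` are skipped.  Codes are normalized.  A data line with
    fewer than two fields raises a ``ValueError`` naming its line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: list[GemEntry] = []
    for lineno, line in enumerate(stream, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.split()
        if len(fields) < 2:
            raise ValueError(
                f"GEM line {lineno}: expected 'source target [flags]', got {text!r}"
            )
        entries.append(
            GemEntry(
                source=normalize_code(fields[0]),
                target=normalize_code(fields[1]),
                direction=direction,
                flags=fields[2] if len(fields) > 2 else "",
            )
        )
    return entries


def build_code_graph(
    observed_codes: Iterable[Node],
    entries: Sequence[GemEntry],
    edge_filter: Callable[[GemEntry], bool] | None = None,
) -> nx.Graph:
    """Build the undirected code-equivalence graph restricted to observed codes.

    Nodes are exactly ``observed_codes`` (as (normalized code, version) pairs);
    an edge exists iff some entry links two observed codes, merging forward and
    backward tables into one undirected relation.  Entries touching unobserved
    codes contribute nothing; their count is logged and stored on
    ``graph.graph["n_dropped_entries"]``.
    """
    nodes = {(normalize_code(c), int(v)) for c, v in observed_codes}
    if not nodes:
        raise ValueError("observed_codes must be non-empty")
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    dropped = 0
    for entry in entries:
        if edge_filter is not None and not edge_filter(entry):
            continue
        a, b = entry.nodes
        if a in nodes and b in nodes:
            graph.add_edge(a, b)
        else:
            dropped += 1
    graph.graph["n_dropped_entries"] = dropped
    if dropped:
        logger.info("dropped %d GEM entries touching unobserved codes", dropped)
    return graph


def connected_components(graph: nx.Graph) -> list[JoinedCode]:
    """Extract connected components as JoinedCode groups.

    Singletons (codes with no equivalence) are legitimate groups.  The result
    is sorted by id, and ids are the smallest member code, so the partition is
    deterministic for a given graph.
    """
    groups = [
        JoinedCode(id=min(code for code, _v in comp), members=frozenset(comp))
        for comp in nx.connected_components(graph)
    ]
    return sorted(groups, key=lambda g: g.id)


def assign_joined_codes(
    records: pd.DataFrame, components: Sequence[JoinedCode]
) -> pd.DataFrame:
    """Return ``records`` with a ``joined_id`` column mapping each death to its group.

    Raises ``KeyError`` if a record's (code, version) appears in no component —
    the symptom of components built from a different cohort.
    """
    mapping: dict[Node, str] = {}
    for comp in components:
        for node in comp.members:
            mapping[node] = comp.id
    keys = list(
        zip(records["cause_code"].map(normalize_code), records["icd_version"].astype(int))
    )
    missing = sorted({k for k in keys if k not in mapping})
    if missing:
        raise KeyError(
            f"codes not covered by any component (components from a different "
            f"cohort?): {missing[:5]}"
        )
    out = records.copy()
    out["joined_id"] = [mapping[k] for k in keys]
    return out


class CodeHarmonizer(BaseEstimator, TransformerMixin):
    """Harmonize raw ICD codes into joined groups, sklearn-transformer style.

    ``fit`` takes the cohort's record frame plus the parsed GEM entries, builds
    the equivalence graph over the codes observed in that frame and extracts
    its connected components.  ``transform`` labels any record frame drawn from
    the same code universe with a ``joined_id`` column.

    Parameters
    ----------
    edge_filter:
        Optional predicate on :class:`GemEntry` deciding which GEM rows may
        create edges (e.g. to exclude approximate mappings).  Default: all rows.

    Attributes
    ----------
    graph_ : networkx.Graph
        The observed-code equivalence graph.
    components_ : list[JoinedCode]
        The harmonized groups (a partition of the observed codes).
    code_to_group_ : dict[(code, version), str]
        Lookup from observed code to its joined id.
    """

    def __init__(self, edge_filter: Callable[[GemEntry], bool] | None = None):
        self.edge_filter = edge_filter

    def fit(self, X: pd.DataFrame, y=None, *, gem_entries: Sequence[GemEntry] = ()):
        observed = {
            (normalize_code(c), int(v))
            for c, v in zip(X["cause_code"], X["icd_version"])
        }
        self.graph_ = build_code_graph(observed, gem_entries, self.edge_filter)
        self.components_ = connected_components(self.graph_)
        self.code_to_group_ = {
            node: comp.id for comp in self.components_ for node in comp.members
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "components_"):
            raise RuntimeError("CodeHarmonizer must be fitted before transform")
        return assign_joined_codes(X, self.components_)


def write_component_table(components: Sequence[JoinedCode], path) -> None:
    """Write components as delimited text: joined_id, member_code, icd_version."""
    rows = [
        {"joined_id": comp.id, "member_code": code, "icd_version": version}
        for comp in components
        for code, version in sorted(comp.members)
    ]
    pd.DataFrame(rows, columns=["joined_id", "member_code", "icd_version"]).to_csv(
        path, sep="\t", index=False
    )
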
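"""Wiring-diagram container and I/O.

A connectome is a directed network over named cells (neurons and muscles)
with three edge types:

* ``chemical`` — directed synaptic connection, neuron → cell;
* ``gap`` — electrical gap junction, stored once and treated as reciprocal
  (expanded to both directions in the adjacency);
* ``nmj`` — neuromuscular junction, neuron → muscle.

Muscles are sinks: they never originate edges.  Source records that violate
this are dropped with a logged warning during normalization, so downstream
control computations can rely on the invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

NEURON = "neuron"
MUSCLE = "muscle"
ETYPES = ("chemical", "gap", "nmj")
CATEGORIES = ("sensory", "interneuron", "motor")


class ConnectomeError(ValueError):
    """Invalid connectome content or operation."""


class FormatError(ConnectomeError):
    """Unparseable or malformed input data."""


@dataclass(frozen=True)
class Cell:
    """A named cell: a neuron (optionally categorized) or a muscle."""

    name: str
    kind: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (NEURON, MUSCLE):
            raise FormatError(f"unknown cell kind {self.kind!r} for {self.name!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise FormatError(f"unknown category {self.category!r} for {self.name!r}")


@dataclass(frozen=True)
class Edge:
    """A stored connection record; gap junctions are stored once."""

    pre: str
    post: str
    etype: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise FormatError(f"unknown edge type {self.etype!r}")
        if self.multiplicity < 1:
            raise FormatError(
                f"multiplicity must be a positive integer, got {self.multiplicity!r}"
            )


def muscle_name_rule(name: str) -> bool:
    """Fallback naming convention: body-wall muscle names begin MV/MD."""
    return name.startswith(("MV", "MD"))


class Connectome:
    """Validated wiring diagram.

    Construction checks the invariants; :meth:`from_records` performs the
    normalization (gap canonicalization, duplicate merging, dropping of
    muscle-originating records) expected of raw data.
    """

    def __init__(self, cells: Iterable[Cell], edges: Iterable[Edge], provenance: str = ""):
        self.cells: dict[str, Cell] = {}
        for cell in cells:
            if cell.name in self.cells:
                raise ConnectomeError(f"duplicate cell name {cell.name!r}")
            self.cells[cell.name] = cell
        if not self.cells:
            raise ConnectomeError("no cells")
        self.edges: tuple[Edge, ...] = tuple(edges)
        self.provenance = provenance
        for e in self.edges:
            for endpoint in (e.pre, e.post):
                if endpoint not in self.cells:
                    raise ConnectomeError(f"edge endpoint {endpoint!r} is not a cell")
            if self.cells[e.pre].kind == MUSCLE:
                raise ConnectomeError(f"muscle {e.pre!r} originates an edge")
            if e.etype == "gap" and self.cells[e.post].kind == MUSCLE:
                raise ConnectomeError(f"gap junction touches muscle {e.post!r}")
            if e.etype == "nmj" and self.cells[e.post].kind != MUSCLE:
                raise ConnectomeError(f"nmj edge must target a muscle, got {e.post!r}")

    # -- derived views ---------------------------------------------------

    @property
    def neurons(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, c in self.cells.items() if c.kind == NEURON))

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, c in self.cells.items() if c.kind == MUSCLE))

    def directed_edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield the deterministic directed-adjacency expansion.

        Gap junctions contribute both directions; order follows the stored
        edge list, so the expansion is reproducible given the records.
        """
        for e in self.edges:
            yield (e.pre, e.post, e.etype)
            if e.etype == "gap":
                yield (e.post, e.pre, e.etype)

    def to_digraph(self) -> nx.DiGraph:
        """Simple directed graph of the adjacency (edge types merged)."""
        g = nx.DiGraph()
        for name, cell in self.cells.items():
            g.add_node(name, kind=cell.kind)
        for pre, post, etype in self.directed_edges():
            if g.has_edge(pre, post):
                g[pre][post]["etypes"] = g[pre][post]["etypes"] + (etype,)
            else:
                g.add_edge(pre, post, etypes=(etype,))
        return g

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        edge_records: Iterable[tuple[str, str, str, int]],
        cell_kinds: Optional[Mapping[str, str]] = None,
        cell_categories: Optional[Mapping[str, str]] = None,
        use_name_rule: bool = True,
        provenance: str = "",
    ) -> "Connectome":
        """Normalize raw records into a validated :class:`Connectome`.

        Cell kinds are resolved from ``cell_kinds`` (authoritative) when
        given; otherwise nmj targets are muscles and, if ``use_name_rule``,
        so is anything matching :func:`muscle_name_rule`.  Normalization:
        duplicate ``(pre, post, etype)`` records have multiplicities summed,
        gap junctions are stored once under a canonical endpoint order, and
        muscle-originating chemical/gap/nmj records are dropped with a
        logged warning.
        """
        records = []
        names: set[str] = set(cell_kinds) if cell_kinds else set()
        for pre, post, etype, mult in edge_records:
            if etype not in ETYPES:
                raise FormatError(f"unknown edge type {etype!r} in record {pre}->{post}")
            try:
                mult = int(mult)
            except (TypeError, ValueError):
                raise FormatError(f"bad multiplicity {mult!r} in record {pre}->{post}")
            records.append((str(pre), str(post), etype, mult))
            names.update((str(pre), str(post)))
        if not names:
            raise ConnectomeError("no cells")

        def kind_of(name: str) -> str:
            if cell_kinds is not None and name in cell_kinds:
                return cell_kinds[name]
            if use_name_rule and muscle_name_rule(name):
                return MUSCLE
            return NEURON

        kinds = {name: kind_of(name) for name in names}
        # nmj targets are muscles by definition; a cells table that says
        # otherwise is a data error, the naming rule merely a fallback.
        for pre, post, etype, _ in records:
            if etype == "nmj":
                if cell_kinds is not None and cell_kinds.get(post) == NEURON:
                    raise FormatError(f"nmj edge targets {post!r}, declared a neuron")
                kinds[post] = MUSCLE

        merged: dict[tuple[str, str, str], int] = {}
        for pre, post, etype, mult in records:
            if kinds[pre] == MUSCLE:
                log.warning("dropping %s edge originating at muscle %s -> %s", etype, pre, post)
                continue
            if etype == "gap":
                if kinds[post] == MUSCLE:
                    log.warning("dropping gap junction touching muscle: %s <-> %s", pre, post)
                    continue
                key = (min(pre, post), max(pre, post), etype)
            else:
                if etype == "nmj" and kinds[post] != MUSCLE:
                    raise FormatError(f"nmj edge must target a muscle, got {post!r}")
                key = (pre, post, etype)
            merged[key] = merged.get(key, 0) + mult

        categories = dict(cell_categories or {})
        cells = [
            Cell(name, kinds[name], categories.get(name))
            for name in sorted(names)
        ]
        edges = [Edge(pre, post, etype, mult) for (pre, post, etype), mult in sorted(merged.items())]
        return cls(cells, edges, provenance=provenance)

    # -- manipulation ----------------------------------------------------

    def ablate(self, removed: Iterable[str]) -> "Connectome":
        """Delete neurons and their incident edges; returns a new connectome.

        Muscles may not be ablated; unknown names are errors.  The original
        connectome is left untouched.
        """
        removed = set(removed)
        for name in removed:
            if name not in self.cells:
                raise ConnectomeError(f"cannot ablate unknown cell {name!r}")
            if self.cells[name].kind == MUSCLE:
                raise ConnectomeError(f"cannot ablate muscle {name!r}")
        cells = [c for n, c in sorted(self.cells.items()) if n not in removed]
        edges = [e for e in self.edges if e.pre not in removed and e.post not in removed]
        return Connectome(cells, edges, provenance=self.provenance)

    # -- equality (as labeled graphs) ------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.cells == other.cells
            and sorted(self.edges, key=lambda e: (e.pre, e.post, e.etype)) ==
            sorted(other.edges, key=lambda e: (e.pre, e.post, e.etype))
        )

    def __repr__(self) -> str:
        return (
            f"<Connectome: {len(self.neurons)} neurons, {len(self.muscles)} muscles, "
            f"{len(self.edges)} edge records>"
        )

    # -- I/O ---------------------------------------------------------------

    def write_edge_csv(self, path: str | Path, cells_path: str | Path | None = None) -> None:
        """Write ``pre,post,etype,multiplicity`` records (gap stored once)."""
        frame = pd.DataFrame(
            [(e.pre, e.post, e.etype, e.multiplicity) for e in self.edges],
            columns=["pre", "post", "etype", "multiplicity"],
        )
        frame.to_csv(path, index=False)
        if cells_path is not None:
            cells = pd.DataFrame(
                [(c.name, c.kind, c.category or "") for c in
                 sorted(self.cells.values(), key=lambda c: c.name)],
                columns=["name", "kind", "category"],
            )
            cells.to_csv(cells_path, index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = nx.MultiDiGraph(provenance=self.provenance)
        for name, cell in self.cells.items():
            g.add_node(name, kind=cell.kind, category=cell.category or "")
        for e in self.edges:
            g.add_edge(e.pre, e.post, etype=e.etype, multiplicity=e.multiplicity)
        nx.write_graphml(g, path)


def _read_cells_table(cells_path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    table = pd.read_csv(cells_path, dtype=str).fillna("")
    for col in ("name", "kind"):
        if col not in table.columns:
            raise FormatError(f"cells table missing column {col!r}")
    kinds = dict(zip(table["name"], table["kind"]))
    categories = {
        n: c for n, c in zip(table["name"], table.get("category", "")) if c
    }
    for name, kind in kinds.items():
        if kind not in (NEURON, MUSCLE):
            raise FormatError(f"unknown kind {kind!r} for cell {name!r}")
    return kinds, categories


def load_connectome(
    path: str | Path,
    format: str = "edge_csv",
    cells_path: str | Path | None = None,
    use_name_rule: bool = True,
) -> Connectome:
    """Read a wiring diagram from ``edge_csv`` or ``graphml``.

    ``edge_csv`` expects a header ``pre,post,etype,multiplicity`` with
    etype in {chemical, gap, nmj}; an optional cells table
    (``name,kind,category``) is authoritative for cell kinds.
    """
    path = Path(path)
    if format == "edge_csv":
        try:
            frame = pd.read_csv(path, dtype={"pre": str, "post": str, "etype": str})
        except pd.errors.EmptyDataError:
            raise ConnectomeError("no cells")
        for col in ("pre", "post", "etype", "multiplicity"):
            if col not in frame.columns:
                raise FormatError(f"edge table missing column {col!r}")
        kinds = categories = None
        if cells_path is not None:
            kinds, categories = _read_cells_table(cells_path)
        return Connectome.from_records(
            frame[["pre", "post", "etype", "multiplicity"]].itertuples(index=False),
            cell_kinds=kinds,
            cell_categories=categories,
            use_name_rule=use_name_rule,
            provenance=f"edge_csv:{path.name}",
        )
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        kinds = {str(n): d.get("kind", "") for n, d in g.nodes(data=True)}
        for name, kind in kinds.items():
            if kind not in (NEURON, MUSCLE):
                if use_name_rule:
                    kinds[name] = MUSCLE if muscle_name_rule(name) else NEURON
                else:
                    raise FormatError(f"graphml node {name!r} missing kind")
        categories = {
            str(n): d["category"]
            for n, d in g.nodes(data=True)
            if d.get("category")
        }
        records = [
            (str(u), str(v), d.get("etype", "chemical"), int(d.get("multiplicity", 1)))
            for u, v, d in g.edges(data=True)
        ]
        if not records and not kinds:
            raise ConnectomeError("no cells")
        return Connectome.from_records(
            records,
            cell_kinds=kinds,
            cell_categories=categories,
            use_name_rule=use_name_rule,
            provenance=f"graphml:{path.name}",
        )
    raise FormatError(f"unknown format {format!r}")
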
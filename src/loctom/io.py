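"""Readers and writers for the plain-text formats the pipeline consumes.

Four kinds of input are supported, all line-oriented text:

* protein interaction edge lists (TSV/CSV, two ID columns plus optional
  per-edge metadata such as a PubMed count or an in-vivo flag),
* protein -> subcellular-location annotation tables (TSV), merged from the
  twelve raw compartment labels down to six major locations,
* reference complex catalogs (one complex per line, MIPS-style),
* flat gene sets (one ID per line).

Identifier handling is deliberately dumb: IDs are case-sensitive,
whitespace-stripped strings and no accession mapping is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .network import Network

logger = logging.getLogger(__name__)

#: The six canonical major subcellular locations.
MAJOR_LOCATIONS: tuple[str, ...] = (
    "nucleus",
    "cytoplasm",
    "membrane",
    "extracellular",
    "mitochondria",
    "secretory-pathway",
)


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class LocationMergeMap:
    """Total mapping from raw compartment labels to major locations.

    Major labels map to themselves, so applying the map twice is a no-op.
    """

    raw_to_major: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {m for m in self.raw_to_major.values() if m not in MAJOR_LOCATIONS}
        if bad:
            raise ValueError(f"merge map targets outside the six major locations: {sorted(bad)}")

    def apply(self, label: str) -> str | None:
        """Return the major label for *label*, or None if unknown."""
        label = label.strip()
        if label in self.raw_to_major:
            return self.raw_to_major[label]
        if label in MAJOR_LOCATIONS:
            return label
        return None

    @classmethod
    def default(cls) -> "LocationMergeMap":
        """The shipped 12 -> 6 compartment scheme."""
        text = resources.files("loctom.data").joinpath("location_merge.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LocationMergeMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass
class LocalizationTable:
    """Protein -> set of major subcellular locations (the localization matrix).

    Every stored label is one of the six canonical major locations and no
    protein maps to an empty set.
    """

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for pid, locs in self.entries.items():
            if not locs:
                raise ValueError(f"protein {pid!r} has an empty location set")
            bad = set(locs) - set(MAJOR_LOCATIONS)
            if bad:
                raise ValueError(f"protein {pid!r} carries non-canonical labels {sorted(bad)}")

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, pid: str) -> frozenset[str]:
        """Location set for *pid*; empty set if unannotated."""
        return self.entries.get(pid, frozenset())


@dataclass
class ComplexCatalog:
    """Reference protein complexes; member sets may overlap between complexes."""

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, members in self.complexes:
            if not members:
                raise ValueError(f"complex {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.complexes]


def _tokenize(path: str | Path, sep: str | None) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split(sep)


def read_edge_list(
    path: str | Path,
    id_columns: tuple[int, int] = (0, 1),
    metadata_columns: Mapping[str, int] | None = None,
    sep: str | None = None,
    header: bool = False,
) -> Network:
    """Read an undirected, simple interaction network from a delimited file.

    Duplicate pairs (in either order) collapse onto one edge; self-pairs are
    recorded on ``Network.self_pairs`` and never become graph edges.
    Metadata columns attach to edges; on duplicate edges the first record wins.
    """
    metadata_columns = metadata_columns or {}
    need = max((*id_columns, *metadata_columns.values()), default=1) + 1
    edges: list[tuple[str, str, dict]] = []
    self_pairs: set[str] = set()
    isolated: list[str] = []
    # "#node <id>" directive lines preserve isolated nodes across round trips
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#node\t") or raw.startswith("#node "):
                isolated.append(raw.split(None, 1)[1].strip())
    for lineno, fields in _tokenize(path, sep):
        if header and lineno == 1:
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
        if len(fields) < need:
            raise FormatError(
                f"{path}:{lineno}: expected >= {need} columns for requested metadata"
            )
        u = fields[id_columns[0]].strip()
        v = fields[id_columns[1]].strip()
        if not u or not v:
            raise FormatError(f"{path}:{lineno}: empty protein identifier")
        meta = {}
        for name, col in metadata_columns.items():
            value = fields[col].strip()
            try:
                meta[name] = float(value) if "." in value or "e" in value else int(value)
            except ValueError:
                meta[name] = value
        if u == v:
            self_pairs.add(u)
            continue
        edges.append((u, v, meta))
    net = Network()
    for u, v, meta in edges:
        net.add_edge(u, v, **meta)
    for u in self_pairs:
        net.add_node(u)
        net.self_pairs.add(u)
    for u in isolated:
        net.add_node(u)
    return net


def write_edge_list(net: Network, path: str | Path, metadata: Sequence[str] = ()) -> None:
    """Write a network in the edge-list dialect :func:`read_edge_list` reads."""
    with open(path, "w") as fh:
        cols = ["node1", "node2", *metadata]
        fh.write("#" + "\t".join(cols) + "\n")
        for u, v in net.edges():
            data = net.edge_data(u, v)
            row = [u, v] + [str(data.get(m, "")) for m in metadata]
            fh.write("\t".join(row) + "\n")
        for u in sorted(net.self_pairs):
            fh.write("\t".join([u, u] + [""] * len(metadata)) + "\n")
        for u in net.nodes:
            if net.degree(u) == 0 and u not in net.self_pairs:
                # isolated nodes survive a round trip as a degenerate comment
                fh.write(f"#node\t{u}\n")


def read_localization(
    path: str | Path,
    merge_map: LocationMergeMap | None = None,
    strict: bool = True,
    sep: str | None = None,
) -> LocalizationTable:
    """Read a protein -> location TSV and merge raw labels to major locations.

    Multiple rows per protein accumulate into its location set. Unknown labels
    raise in strict mode (the default) and are dropped with a logged count
    otherwise — silently losing annotation would corrupt downstream
    co-localization filtering.
    """
    merge_map = merge_map or LocationMergeMap.default()
    entries: dict[str, set[str]] = {}
    dropped = 0
    for lineno, fields in _tokenize(path, sep):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected protein and location columns")
        pid = fields[0].strip()
        # location labels may contain internal spaces ("plasma membrane")
        raw = " ".join(f.strip() for f in fields[1:])
        major = merge_map.apply(raw)
        if major is None:
            if strict:
                raise FormatError(f"{path}:{lineno}: unknown location label {raw!r}")
            dropped += 1
            continue
        entries.setdefault(pid, set()).add(major)
    if dropped:
        logger.warning("dropped %d rows with unknown location labels", dropped)
    return LocalizationTable({p: frozenset(s) for p, s in entries.items() if s})


def write_localization(table: LocalizationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein\tlocation\n")
        for pid in sorted(table.entries):
            for loc in sorted(table.entries[pid]):
                fh.write(f"{pid}\t{loc}\n")


def read_complex_catalog(
    path: str | Path,
    min_size: int = 3,
    max_size: int = 100,
    first_token_is_id: bool = True,
) -> ComplexCatalog:
    """Read a MIPS-style catalog: one complex per line, tab/space separated.

    Complexes with fewer than *min_size* or more than *max_size* members are
    excluded; the defaults keep sizes 3..100.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    n_seen = 0
    for lineno, fields in _tokenize(path, None):
        n_seen += 1
        if first_token_is_id:
            cid, members = fields[0], fields[1:]
        else:
            cid, members = f"C{lineno}", fields
        member_set = frozenset(m.strip() for m in members if m.strip())
        if not member_set:
            raise FormatError(f"{path}:{lineno}: complex {cid!r} has no members")
        if min_size <= len(member_set) <= max_size:
            complexes.append((cid, member_set))
    if n_seen == 0:
        raise FormatError(f"{path}: empty complex catalog")
    return ComplexCatalog(complexes)


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, members in catalog.complexes:
            fh.write("\t".join([cid, *sorted(members)]) + "\n")


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-ID-per-line gene set; blank lines and # comments skipped."""
    genes: set[str] = set()
    for _, fields in _tokenize(path, None):
        genes.add(fields[0].strip())
    if not genes:
        warnings.warn(f"{path}: gene set is empty", stacklevel=2)
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
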
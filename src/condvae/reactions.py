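"""Condensed graphs of reaction and fragment-count descriptors.

A mapped reaction (atom-map numbers pairing reactant and product atoms) is
collapsed into a single *condensed graph of reaction* (CGR): one
pseudomolecular graph over the union of mapped atoms, where each bond carries
the pair (reactant order, product order). Bonds whose order differs between
the two sides are *dynamic bonds*; atoms whose formal charge changes are
*dynamic atoms*. The CGR therefore encodes the whole transformation —
including broken/formed bonds — as one molecular-graph-like object.

Descriptors are counts of atom-and-bond path fragments of 2–4 atoms
(sequence length counted in atoms), optionally annotated with formal charges,
compressed with incremental PCA to the dimensionality that explains ~95% of
the variance of the training corpus.

Fragment dialect (any self-consistent encoding is admissible; this one is
documented here and frozen): atom labels are element symbols, with ``{+n}``
charge suffixes when charge annotation is on and ``{r>p}`` for dynamic atoms;
bond labels are ``-`` ``=`` ``#`` ``:`` for single/double/triple/aromatic and
``.`` for a bond absent on one side, with dynamic bonds written
``<r-label>'>'<p-label>`` (e.g. ``=>-`` for a double bond reduced to single).
An undirected path and its reverse are the same fragment; the
lexicographically smaller of the two directional strings is the canonical
key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from sklearn.decomposition import IncrementalPCA

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MappedReaction", "FragmentTable", "DescriptorCompressor",
    "parse_mapped_reaction", "build_cgr", "enumerate_fragments",
    "fit_compressor", "apply_compressor", "ReactionParseError",
]


class ReactionParseError(ValueError):
    pass


_BOND_CHAR = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":", None: "."}


@dataclass
class MappedReaction:
    """Mapped reactant/product graphs plus the reagents that carry no map.

    Graphs are ``networkx.Graph`` objects with node attributes ``element``,
    ``charge``, ``aromatic``, ``map_num`` (0 for unmapped) and edge attribute
    ``order`` (1, 2, 3 or 1.5 for aromatic). Hydrogens are implicit.
    """

    reactants: list[nx.Graph]
    products: list[nx.Graph]
    reagents: list[str] = field(default_factory=list)  # unmapped species, as SMILES
    smiles: str = ""

    def mapped_side(self, side: str) -> dict[int, dict]:
        """map_num -> atom attrs over all graphs of one side."""
        graphs = self.reactants if side == "reactant" else self.products
        out: dict[int, dict] = {}
        for g in graphs:
            for n, attrs in g.nodes(data=True):
                if attrs["map_num"]:
                    out[attrs["map_num"]] = attrs
        return out

    def mapped_bonds(self, side: str) -> dict[frozenset, float]:
        """{map_a, map_b} -> bond order, restricted to mapped atom pairs."""
        graphs = self.reactants if side == "reactant" else self.products
        out: dict[frozenset, float] = {}
        for g in graphs:
            for a, b, attrs in g.edges(data=True):
                ma, mb = g.nodes[a]["map_num"], g.nodes[b]["map_num"]
                if ma and mb:
                    out[frozenset((ma, mb))] = attrs["order"]
        return out


def _mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol(),
                   charge=atom.GetFormalCharge(),
                   aromatic=atom.GetIsAromatic(),
                   map_num=atom.GetAtomMapNum())
    for bond in mol.GetBonds():
        order = 1.5 if bond.GetIsAromatic() else float(bond.GetBondTypeAsDouble())
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=order)
    return g


def parse_mapped_reaction(text: str) -> MappedReaction:
    """Parse one reaction-SMILES line into mapped reactant/product graphs.

    Species without any atom-map number (e.g. unmapped H₂) are dropped from
    graph construction and kept as `reagents` metadata. Explicit hydrogens are
    removed by RDKit sanitization. Raises :class:`ReactionParseError` for
    malformed SMILES, missing mapped atoms on either side, or a duplicated
    map number on one side.
    """
    line = text.strip()
    if line.count(">>") != 1:
        # tolerate the reagent form a>b>c by collapsing the middle as reagents
        parts = line.split(">")
        if len(parts) != 3:
            raise ReactionParseError(f"expected '>>' separator in {line!r}")
        left, mid, right = parts
        line = f"{left}.{mid}>>{right}" if mid else f"{left}>>{right}"
    lhs, rhs = line.split(">>")

    def parse_side(side_smiles: str, side: str):
        graphs, reagents = [], []
        seen_maps: set[int] = set()
        for token in filter(None, side_smiles.split(".")):
            mol = Chem.MolFromSmiles(token)
            if mol is None:
                raise ReactionParseError(f"unparsable SMILES {token!r} in {text.strip()!r}")
            mol = Chem.RemoveHs(mol)
            maps = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()]
            if not maps:
                reagents.append(token)
                continue
            for m in maps:
                if m in seen_maps:
                    raise ReactionParseError(
                        f"map number {m} duplicated on {side} side of {text.strip()!r}")
                seen_maps.add(m)
            graphs.append(_mol_to_graph(mol))
        return graphs, reagents

    reactant_graphs, lhs_reagents = parse_side(lhs, "reactant")
    product_graphs, rhs_reagents = parse_side(rhs, "product")
    if not reactant_graphs or not product_graphs:
        raise ReactionParseError(f"no mapped atoms on one side of {text.strip()!r}")
    return MappedReaction(reactant_graphs, product_graphs,
                          lhs_reagents + rhs_reagents, line)


def build_cgr(rxn: MappedReaction) -> nx.Graph:
    """Collapse a mapped reaction into its condensed graph of reaction.

    Nodes are map numbers with attributes ``element``, ``charge_r``,
    ``charge_p`` (``None`` when the atom is absent on that side) and
    ``dynamic``; edges carry ``order_r``, ``order_p`` (``None`` for a bond
    absent on that side) and ``dynamic`` (orders differ).
    """
    r_atoms = rxn.mapped_side("reactant")
    p_atoms = rxn.mapped_side("product")
    cgr = nx.Graph()
    for m in sorted(set(r_atoms) | set(p_atoms)):
        ra, pa = r_atoms.get(m), p_atoms.get(m)
        element = (ra or pa)["element"]
        if ra and pa and ra["element"] != pa["element"]:
            raise ReactionParseError(f"map number {m} changes element "
                                     f"({ra['element']}→{pa['element']})")
        charge_r = ra["charge"] if ra else None
        charge_p = pa["charge"] if pa else None
        cgr.add_node(m, element=element, charge_r=charge_r, charge_p=charge_p,
                     dynamic=charge_r != charge_p)
    r_bonds = rxn.mapped_bonds("reactant")
    p_bonds = rxn.mapped_bonds("product")
    for pair in set(r_bonds) | set(p_bonds):
        a, b = sorted(pair)
        o_r, o_p = r_bonds.get(pair), p_bonds.get(pair)
        cgr.add_edge(a, b, order_r=o_r, order_p=o_p, dynamic=o_r != o_p)
    return cgr


@dataclass
class FragmentTable:
    """Canonical fragment key → count, with the enumeration settings used."""

    counts: dict[str, int]
    min_len: int
    max_len: int
    charges: bool = False

    def vector(self, vocabulary: tuple[str, ...]) -> np.ndarray:
        return np.array([self.counts.get(k, 0) for k in vocabulary], dtype=np.float64)


def _atom_label(attrs: dict, charges: bool) -> str:
    label = attrs["element"]
    if not charges:
        return label
    cr, cp = attrs.get("charge_r"), attrs.get("charge_p")
    if cr is None and cp is None:
        c = attrs.get("charge", 0)
        return label if c == 0 else f"{label}{{{c:+d}}}"
    if attrs.get("dynamic"):
        fr = "." if cr is None else f"{cr:+d}"
        fp = "." if cp is None else f"{cp:+d}"
        return f"{label}{{{fr}>{fp}}}"
    return label if cr == 0 else f"{label}{{{cr:+d}}}"


def _bond_label(attrs: dict) -> str:
    if "order" in attrs:  # plain molecular graph
        return _BOND_CHAR[attrs["order"]]
    o_r, o_p = attrs.get("order_r"), attrs.get("order_p")
    if attrs.get("dynamic"):
        return f"{_BOND_CHAR[o_r]}>{_BOND_CHAR[o_p]}"
    return _BOND_CHAR[o_r]


def enumerate_fragments(cgr: nx.Graph, min_len: int = 2, max_len: int = 4,
                        charges: bool = False) -> FragmentTable:
    """Count canonical simple-path fragments of `min_len`..`max_len` atoms.

    Every simple path (no repeated atoms) is counted once: the two directional
    readings of a path produce two strings and the lexicographically smaller
    one is the key. Works on CGRs and on plain molecular graphs.
    """
    if min_len < 1:
        raise ValueError("min_len must be ≥ 1")
    if max_len < min_len:
        raise ValueError("max_len must be ≥ min_len")
    atom_labels = {n: _atom_label(attrs, charges) for n, attrs in cgr.nodes(data=True)}
    bond_labels = {frozenset((a, b)): _bond_label(attrs)
                   for a, b, attrs in cgr.edges(data=True)}
    counts: dict[str, float] = {}

    def path_string(path: list) -> str:
        parts = [atom_labels[path[0]]]
        for a, b in zip(path, path[1:]):
            parts.append(bond_labels[frozenset((a, b))])
            parts.append(atom_labels[b])
        return "".join(parts)

    if min_len == 1:
        for n in cgr.nodes:
            key = atom_labels[n]
            counts[key] = counts.get(key, 0) + 1

    # directed DFS; every undirected path of ≥2 atoms is visited exactly twice
    def extend(path: list):
        if len(path) >= max(2, min_len) and len(path) <= max_len:
            s = path_string(path)
            key = min(s, path_string(path[::-1]))
            counts[key] = counts.get(key, 0) + 0.5
        if len(path) >= max_len:
            return
        for nbr in cgr.neighbors(path[-1]):
            if nbr not in path:
                path.append(nbr)
                extend(path)
                path.pop()

    for start in cgr.nodes:
        extend([start])
    table = {k: int(round(v)) for k, v in counts.items() if round(v) >= 1}
    return FragmentTable(table, min_len, max_len, charges)


@dataclass
class DescriptorCompressor:
    """Frozen incremental-PCA projection of fragment-count vectors.

    `components` is (D, |vocabulary|); unseen fragment keys contribute zero
    counts. Fit on the training corpus only; queries are transformed with the
    frozen projection.
    """

    vocabulary: tuple[str, ...]
    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    scale: np.ndarray | None = None   # per-component std on fit data (whitening)

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    def _project(self, centered: np.ndarray) -> np.ndarray:
        out = centered @ self.components.T
        if self.scale is not None:
            out = out / self.scale
        return out

    def transform(self, table: FragmentTable) -> np.ndarray:
        return self._project(table.vector(self.vocabulary) - self.mean)

    def transform_corpus(self, tables) -> np.ndarray:
        X = np.stack([t.vector(self.vocabulary) for t in tables])
        return self._project(X - self.mean)


def fit_compressor(tables, target_variance: float = 0.95,
                   max_dim: int = 500, batch_size: int | None = None,
                   whiten: bool = True) -> DescriptorCompressor:
    """Fit incremental PCA on a fragment-table corpus.

    The retained dimension is the smallest that reaches `target_variance`
    cumulative explained variance, capped at `max_dim`. The vocabulary is the
    lexicographically sorted union of fragment keys (deterministic). With
    `whiten` (default) each retained component is rescaled to unit variance
    on the fit corpus, which conditions the downstream network inputs.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("empty corpus")
    vocabulary = tuple(sorted(set().union(*(t.counts.keys() for t in tables))))
    X = np.stack([t.vector(vocabulary) for t in tables])
    n, v = X.shape
    k = min(max_dim, n, v)
    ipca = IncrementalPCA(n_components=k, batch_size=batch_size or max(5 * k, 64))
    ipca.fit(X)
    cum = np.cumsum(ipca.explained_variance_ratio_)
    reached = np.searchsorted(cum, target_variance) + 1
    d = int(min(max(reached, 1), k))
    scale = None
    if whiten:
        proj = (X - ipca.mean_) @ ipca.components_[:d].T
        scale = np.maximum(proj.std(axis=0), 1e-8)
    return DescriptorCompressor(
        vocabulary=vocabulary,
        mean=ipca.mean_.copy(),
        components=ipca.components_[:d].copy(),
        explained_variance_ratio=ipca.explained_variance_ratio_[:d].copy(),
        scale=scale,
    )


def apply_compressor(comp: DescriptorCompressor, table: FragmentTable) -> np.ndarray:
    """Project one fragment table to the compressed descriptor vector x."""
    return comp.transform(table)


# ---------------------------------------------------------------------------
# plain-text IO: reaction lists, fragment corpora, descriptor matrices
# ---------------------------------------------------------------------------
def read_reaction_smiles(path) -> list[tuple[str, str]]:
    """Read '<smiles>' or '<smiles>\\t<id>' lines; '#' comments skipped."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rid = parts[1] if len(parts) > 1 else f"rxn_{i}"
            out.append((parts[0], rid))
    return out


def read_rdf(path) -> list[tuple[str, str]]:
    """Extract mapped reaction SMILES from an MDL RDF file via RDKit."""
    from rdkit.Chem import rdChemReactions

    with open(path) as fh:
        content = fh.read()
    out = []
    blocks = content.split("$RXN")[1:]
    for i, block in enumerate(blocks):
        rxn_block = "$RXN" + block.split("$RFMT")[0].split("$DTYPE")[0]
        rxn = rdChemReactions.ReactionFromRxnBlock(rxn_block)
        if rxn is None:
            raise ReactionParseError(f"unparsable $RXN record #{i} in {path}")
        out.append((rdChemReactions.ReactionToSmiles(rxn), f"rdf_{i}"))
    return out


def write_fragment_corpus(path, tables: dict[str, FragmentTable]) -> None:
    """Sparse triplet TSV: reaction_id, fragment_key, count."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tfragment_key\tcount\n")
        for rid, table in tables.items():
            for key in sorted(table.counts):
                fh.write(f"{rid}\t{key}\t{table.counts[key]}\n")


def read_fragment_corpus(path, min_len: int = 2, max_len: int = 4,
                         charges: bool = False) -> dict[str, FragmentTable]:
    tables: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, key, count = line.rstrip("\n").split("\t")
            tables.setdefault(rid, {})[key] = int(count)
    return {rid: FragmentTable(c, min_len, max_len, charges) for rid, c in tables.items()}


def write_descriptor_matrix(path, ids: list[str], X: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\t" + "\t".join(f"pc_{i}" for i in range(X.shape[1])) + "\n")
        for rid, row in zip(ids, X):
            fh.write(rid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
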
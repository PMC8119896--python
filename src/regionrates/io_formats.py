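"""Readers, writers, and the shared data model.

Everything the pipeline touches on disk goes through this module: FASTA
multiple sequence alignments of orthogroups, Newick phylogenies, TSV
per-residue feature tables, and PaxDb-style abundance tables.  Readers
validate their input into the in-memory containers used downstream
(:class:`OrthoGroup`, :class:`PhyloTree`, pandas DataFrames with a fixed
column schema) and fail loudly rather than silently dropping rows.

Conventions fixed here once for the whole package:

* residue positions are 1-based and inclusive;
* amino acids are the 20 standard one-letter codes, parsed
  case-insensitively; ``-``, ``.`` and ``*`` are gaps; any other letter is
  normalized to the unknown character ``X``;
* result tables are TSV with ``.`` as decimal separator and no thousands
  separators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("regionrates.io")

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHAR = "-"
UNKNOWN_CHAR = "X"
N_STATES = 20
GAP_CODE = 20
UNKNOWN_CODE = 21

_GAP_EQUIVALENTS = {"-", ".", "*"}


class RegionRatesError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RegionRatesError, ValueError):
    """Malformed input file (ragged alignment, bad Newick, missing columns)."""


class RangeError(RegionRatesError, ValueError):
    """A bounded field is out of range (rASA outside [0, 1], negative ppm)."""


class IntegrityError(RegionRatesError, ValueError):
    """Structural inconsistency (duplicate positions, missing reference)."""


class EstimationError(RegionRatesError, RuntimeError):
    """An estimator has no informative data to work with."""


class ConfigurationError(RegionRatesError, ValueError):
    """Invalid configuration value or unknown identifier."""


def normalize_residue(char: str) -> str:
    """Map one alignment character onto the package alphabet.

    Upper-cases the input, maps ``-``/``.``/``*`` to the gap character and
    any letter that is not one of the 20 standard amino acids to ``X``.
    """
    c = char.upper()
    if c in _GAP_EQUIVALENTS:
        return GAP_CHAR
    if c in AA_INDEX:
        return c
    return UNKNOWN_CHAR


def normalize_sequence(seq: str) -> str:
    return "".join(normalize_residue(c) for c in seq)


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode a normalized aligned sequence (gap=20, unknown=21)."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq):
        if c == GAP_CHAR:
            out[i] = GAP_CODE
        elif c == UNKNOWN_CHAR:
            out[i] = UNKNOWN_CODE
        else:
            out[i] = AA_INDEX[c]
    return out


# ---------------------------------------------------------------------------
# OrthoGroup
# ---------------------------------------------------------------------------


@dataclass
class OrthoGroup:
    """A multiple sequence alignment of orthologous proteins.

    One sequence per taxon, all of identical aligned length, over the
    20 amino acids plus gap and unknown.  ``reference_taxon`` names the
    species whose (ungapped) sequence defines residue positions.
    """

    group_id: str
    taxa: list[str]
    sequences: list[str]  # aligned, normalized, parallel to ``taxa``
    reference_taxon: str

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise IntegrityError(
                f"orthogroup {self.group_id}: {len(self.taxa)} taxa but "
                f"{len(self.sequences)} sequences"
            )
        if len(self.taxa) < 2:
            raise FormatError(f"orthogroup {self.group_id}: needs >= 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(
                f"orthogroup {self.group_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if self.taxa.count(self.reference_taxon) != 1:
            raise IntegrityError(
                f"orthogroup {self.group_id}: reference taxon "
                f"{self.reference_taxon!r} present {self.taxa.count(self.reference_taxon)} "
                "times (must be exactly once)"
            )

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def sequence_for(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    @property
    def reference_sequence(self) -> str:
        return self.sequence_for(self.reference_taxon)

    def matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) uint8 code matrix."""
        return np.vstack([encode_sequence(s) for s in self.sequences])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthoGroup):
            return NotImplemented
        return (
            self.group_id == other.group_id
            and self.taxa == other.taxa
            and self.sequences == other.sequences
            and self.reference_taxon == other.reference_taxon
        )


def read_msa_fasta(path: str | Path, reference_taxon: str, group_id: str | None = None) -> OrthoGroup:
    """Read one orthogroup alignment from a FASTA file.

    Record ids are taxon ids.  Sequences are normalized (case, gap
    equivalents, unknown letters).  A ragged alignment raises
    :class:`FormatError` naming the offending record; a missing reference
    taxon raises :class:`IntegrityError`.
    """
    path = Path(path)
    taxa: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(normalize_sequence(str(rec.seq)))
    if not taxa:
        raise FormatError(f"{path}: no FASTA records found")
    n0 = len(seqs[0])
    for t, s in zip(taxa, seqs):
        if len(s) != n0:
            raise FormatError(
                f"{path}: ragged alignment, record {t!r} has length {len(s)}, "
                f"expected {n0}"
            )
    if reference_taxon not in taxa:
        raise IntegrityError(f"{path}: reference taxon {reference_taxon!r} not found")
    return OrthoGroup(
        group_id=group_id or path.stem,
        taxa=taxa,
        sequences=seqs,
        reference_taxon=reference_taxon,
    )


def write_msa_fasta(group: OrthoGroup, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(group.taxa, group.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny with branch lengths, indexed for fast traversal.

    Nodes are integers; ``parent[i]`` is the parent index (root has -1) and
    ``branch_lengths[i]`` is the length of the edge above node *i* in
    expected substitutions per site.  ``leaf_labels`` maps leaf node index
    to taxon id.  Branch lengths missing from the source Newick default to
    0 (an identity transition), with a logged warning.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_lengths: Sequence[float],
        leaf_labels: Mapping[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        if self.parent.shape != self.branch_lengths.shape:
            raise IntegrityError("parent and branch_lengths must be parallel arrays")
        if np.any(~np.isfinite(self.branch_lengths)) or np.any(self.branch_lengths < 0):
            raise RangeError("branch lengths must be finite and >= 0")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise IntegrityError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[int(self.parent[i])].append(i)
        self.leaf_labels = dict(leaf_labels)
        leaves = [i for i in range(n) if not self.children[i]]
        missing = [i for i in leaves if i not in self.leaf_labels]
        if missing:
            raise IntegrityError(f"unlabeled leaf nodes: {missing}")
        if len(set(self.leaf_labels.values())) != len(self.leaf_labels):
            raise IntegrityError("duplicate leaf labels")
        self.leaf_index = {lab: i for i, lab in self.leaf_labels.items()}
        self.postorder = self._compute_postorder()

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for child in reversed(self.children[node]):
                    stack.append((child, False))
        return np.asarray(order, dtype=np.int64)

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def root_to_tip_lengths(self) -> dict[str, float]:
        depth = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.branch_lengths[node]
        return {lab: float(depth[i]) for i, lab in self.leaf_labels.items()}

    def scaled(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.parent, self.branch_lengths * factor, self.leaf_labels)

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """Patristic leaf-to-leaf distances (for round-trip comparisons)."""
        # path to root per leaf, then distance via lowest common ancestor
        taxa = self.taxa
        anc: dict[str, dict[int, float]] = {}
        for lab in taxa:
            node = self.leaf_index[lab]
            d = 0.0
            chain = {}
            while node >= 0:
                chain[node] = d
                if node == self.root:
                    break
                d += float(self.branch_lengths[node])
                node = int(self.parent[node])
            anc[lab] = chain
        mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                common = min(
                    (anc[a][n] + anc[b][n] for n in anc[a] if n in anc[b]),
                )
                mat.loc[a, b] = mat.loc[b, a] = common
        return mat

    # -- Newick -------------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        leaf_labels: dict[int, str] = {}
        n_missing = 0
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    n_missing += 1
                else:
                    blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise FormatError("leaf without a label in Newick input")
                leaf_labels[i] = label.replace(" ", "_")
        if n_missing:
            logger.warning(
                "%d branch length(s) missing from Newick input; defaulting to 0",
                n_missing,
            )
        return cls(parent, blen, leaf_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"invalid Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.is_leaf(node):
                body = self.leaf_labels[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return body
            return f"{body}:{self.branch_lengths[node]:.17g}"

        return render(self.root) + ";"


def read_newick(path: str | Path) -> PhyloTree:
    """Read a phylogeny from a Newick file."""
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty Newick file")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Per-residue features and protein metadata
# ---------------------------------------------------------------------------


@dataclass
class ResidueFeature:
    """One residue of one protein, with its structural and evolutionary data."""

    protein_id: str
    position: int  # 1-based
    amino_acid: str
    rasa: float = math.nan
    disorder_prob: float = math.nan
    in_domain: bool = False
    domain_evalue: float = math.nan
    rate: float = math.nan


@dataclass
class ProteinMeta:
    protein_id: str
    length: int
    abundance_ppm: float = math.nan
    orthogroup_id: str | None = None
    has_pdb_structure: bool = False


FEATURE_COLUMNS = [
    "protein_id",
    "position",
    "amino_acid",
    "rasa",
    "disorder_prob",
    "in_domain",
    "domain_evalue",
    "rate",
]
_REQUIRED_FEATURE_COLUMNS = ["protein_id", "position", "amino_acid"]
_BOUNDED_COLUMNS = ["rasa", "disorder_prob"]


def validate_feature_frame(df: pd.DataFrame, check_contiguous: bool = True) -> pd.DataFrame:
    """Validate and canonicalize a residue feature table.

    Sorts by (protein_id, position), checks position uniqueness and (by
    default) contiguity from 1, and range-checks bounded columns.  Missing
    optional columns are added filled with NA.
    """
    for col in _REQUIRED_FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"feature table missing required column {col!r}")
    df = df.copy()
    df["position"] = df["position"].astype(np.int64)
    df["amino_acid"] = df["amino_acid"].astype(str).map(normalize_residue)
    for col in _BOUNDED_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RangeError(
                f"feature table: {col}={vals.iloc[row]} out of [0, 1] at row {row} "
                f"(protein {df['protein_id'].iloc[row]}, position {df['position'].iloc[row]})"
            )
        df[col] = vals
    if "in_domain" not in df.columns:
        df["in_domain"] = False
    else:
        df["in_domain"] = (
            df["in_domain"]
            .map(lambda v: str(v).strip().lower() in {"true", "1", "t", "yes"})
            .astype(bool)
        )
    for col in ("domain_evalue", "rate"):
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(subset=["protein_id", "position"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate residue (protein {row['protein_id']}, position {row['position']})"
        )
    df = df.sort_values(["protein_id", "position"], kind="mergesort").reset_index(drop=True)
    if check_contiguous:
        for pid, grp in df.groupby("protein_id", sort=False):
            pos = grp["position"].to_numpy()
            if pos[0] != 1 or np.any(np.diff(pos) != 1):
                raise IntegrityError(
                    f"protein {pid}: positions not contiguous from 1 "
                    f"(first {pos[0]}, last {pos[-1]}, n {len(pos)})"
                )
    return df[FEATURE_COLUMNS]


def read_feature_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    check_contiguous: bool = True,
) -> pd.DataFrame:
    """Read a per-residue feature TSV into the canonical column schema.

    ``columns`` maps canonical names (see :data:`FEATURE_COLUMNS`) to the
    file's column names, accommodating foreign schemas.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return validate_feature_frame(df, check_contiguous=check_contiguous)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_abundance_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Read a PaxDb-style abundance TSV into a protein_id -> ppm map.

    Lines starting with ``#`` are skipped.  Duplicate protein ids keep the
    first occurrence with a logged warning; negative ppm raises
    :class:`RangeError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    for col in ("protein_id", "ppm"):
        if col not in df.columns:
            raise FormatError(f"abundance table missing column {col!r}")
    ppm = pd.to_numeric(df["ppm"], errors="coerce")
    if (ppm < 0).any():
        row = int(np.flatnonzero((ppm < 0).to_numpy())[0])
        raise RangeError(
            f"abundance table: negative ppm {ppm.iloc[row]} for protein "
            f"{df['protein_id'].iloc[row]}"
        )
    dup = df["protein_id"].duplicated()
    if dup.any():
        logger.warning(
            "abundance table: %d duplicate protein id(s); keeping first occurrence",
            int(dup.sum()),
        )
        df = df.loc[~dup]
        ppm = ppm.loc[~dup]
    return dict(zip(df["protein_id"].astype(str), ppm.astype(float)))


def write_abundance_table(abundance: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        {"protein_id": list(abundance.keys()), "ppm": list(abundance.values())}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Read a domain-interval TSV (protein_id, start, end, evalue)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("protein_id", "start", "end", "evalue"):
        if col not in df.columns:
            raise FormatError(f"domain table missing column {col!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
    if (df["evalue"] <= 0).any():
        raise RangeError("domain table: E-values must be positive")
    return df


def write_domain_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a generic result table (TSV, '.' decimals, fixed float format)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
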
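"""Sequence I/O and greedy identity-threshold clustering.

Seed sets for profile building are de-redundified by clustering at a
fractional-identity threshold (0.50 by default), in the CD-HIT spirit:
sequences are considered longest-first, each joins the first existing
cluster whose representative it matches at or above the threshold, and
otherwise founds a new cluster.  Identity between two sequences is the
number of identical aligned residue pairs in one optimal global alignment,
divided by the length of the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20-letter alphabet plus X.

    Parameters
    ----------
    id : str
        Identifier, unique within a file.
    residues : str
        Amino-acid string; upper-cased on validation.
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"protein alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapping via Biopython)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an alignment (aligned FASTA or Stockholm), columns preserved.

    Returns a list of ``(id, aligned_row)`` pairs; gap characters ``-`` and
    ``.`` are normalised to ``-``.
    """
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in aln]


def write_alignment(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    bio = [_BioSeqRecord(Seq(row), id=rid, description="") for rid, row in rows]
    SeqIO.write(bio, str(path), "fasta")


def subset_alignment(
    rows: Sequence[tuple[str, str]], ids: Iterable[str]
) -> list[tuple[str, str]]:
    """Restrict an alignment to the given ids, dropping all-gap columns.

    Row order follows the original alignment; remaining columns keep their
    relative order, so homologous positions stay aligned.
    """
    wanted = set(ids)
    kept = [(rid, row) for rid, row in rows if rid in wanted]
    if not kept:
        raise ValueError("no alignment rows match the requested ids")
    missing = wanted - {rid for rid, _ in kept}
    if missing:
        raise KeyError(f"ids absent from the alignment: {sorted(missing)}")
    width = len(kept[0][1])
    keep_cols = [c for c in range(width) if any(row[c] != GAP for _, row in kept)]
    return [(rid, "".join(row[c] for c in keep_cols)) for rid, row in kept]


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterParams:
    """Parameters of the identity computation and clustering.

    identity_threshold is a fraction in (0, 1]; the de-redundification
    default is 0.50.  Alignment uses a global (Needleman-Wunsch) alignment
    under a standard substitution matrix with affine gap penalties.
    """

    identity_threshold: float = 0.50
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class Clustering:
    """Result of greedy clustering: representative ids and their members."""

    clusters: list[tuple[str, list[str]]]
    params: ClusterParams = field(default_factory=ClusterParams)

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("representative\tmember\n")
            for rep, members in self.clusters:
                for m in members:
                    fh.write(f"{rep}\t{m}\n")


def _make_aligner(params: ClusterParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: ClusterParams | None = None,
    _aligner: PairwiseAligner | None = None,
) -> float:
    """Fractional identity between two sequences.

    Computed as (identical aligned residue pairs) / (length of the shorter
    sequence) over one optimal global alignment.  Symmetric in its
    arguments and equal to 1.0 for identical sequences.
    """
    params = params or ClusterParams()
    aligner = _aligner if _aligner is not None else _make_aligner(params)
    aln = aligner.align(a.residues, b.residues)[0]
    identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for x, y in zip(a.residues[a0:a1], b.residues[b0:b1]):
            if x == y:
                identical += 1
    return identical / min(len(a), len(b))


def cluster_at_identity(
    seqs: Sequence[SequenceRecord], params: ClusterParams | None = None
) -> Clustering:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are sorted by length descending (ties broken by id
    ascending); each sequence joins the first representative, in founding
    order, with identity >= the threshold, otherwise it founds a new
    cluster.  The result is a partition: every input id appears exactly
    once, every representative belongs to its own cluster, and all pairs of
    representatives have identity strictly below the threshold.
    """
    if not seqs:
        raise ValueError("cluster_at_identity requires at least one sequence")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    params = params or ClusterParams()
    aligner = _make_aligner(params)
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for seq in ordered:
        for i, rep in enumerate(reps):
            ident = pairwise_identity(seq, rep, params, _aligner=aligner)
            if ident >= params.identity_threshold:
                members[i].append(seq.id)
                break
        else:
            reps.append(seq)
            members.append([seq.id])
    return Clustering(
        clusters=[(rep.id, mem) for rep, mem in zip(reps, members)], params=params
    )
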
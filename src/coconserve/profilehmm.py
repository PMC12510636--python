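"""Profile hidden Markov models: build, score in bits, calibrate E-values.

The model follows the classical profile-HMM architecture (match, insert
and delete states per alignment column, with all nine M/I/D transition
types) traversed glocally: every path runs begin -> (column 1 .. column L)
-> end, with sequence flanks absorbed by the first and last insert states.
Scores are log-odds in bits against an i.i.d. background null of the same
length, so insert states that emit background frequencies contribute
nothing and the bit score measures match-state evidence.

E-values come from an extreme-value (Gumbel) fit to forward bit scores of
random background sequences: E(S) = db_size * P_gumbel(score >= S).

State bookkeeping
-----------------
Match states are numbered 1..L; the begin state is treated as M_0 and the
end state as M_{L+1}.  Insert states I_0..I_L sit between columns (I_0
before column 1 absorbs N-terminal flank, I_L after column L absorbs
C-terminal flank).  Delete states are D_1..D_L.  Transition probability
arrays are indexed by source state:

====  ==========================  ======
key   meaning                     length
====  ==========================  ======
MM    M_k -> M_{k+1}, k=0..L      L+1
MI    M_k -> I_k,     k=0..L      L+1
MD    M_k -> D_{k+1}, k=0..L-1    L
IM    I_k -> M_{k+1}, k=0..L      L+1
II    I_k -> I_k,     k=0..L      L+1
ID    I_k -> D_{k+1}, k=0..L-1    L
DM    D_k -> M_{k+1}, k=1..L      L
DD    D_k -> D_{k+1}, k=1..L-1    L-1
DI    D_k -> I_k,     k=1..L      L
====  ==========================  ======
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy import optimize, stats

from .seqcluster import AMINO_ACIDS, GAP, SequenceRecord

LN2 = math.log(2.0)
NEG_INF = -np.inf

_AA_TO_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_TO_IDX["X"] = 20  # scored as background (log-odds 0)

#: Background residue frequencies of the null model: uniform over the 20
#: amino acids by default (the synthetic generator draws from the same
#: distribution, keeping model and null consistent on generated data).
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

_TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI")


def encode_sequence(residues: str) -> np.ndarray:
    """Encode residues as integer indices (X -> 20)."""
    try:
        return np.array([_AA_TO_IDX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue outside the protein alphabet: {exc}") from exc


@dataclass
class Calibration:
    """Gumbel parameters of the null score distribution.

    ``gumbel_mu`` is the location and ``gumbel_lambda`` the inverse scale of
    the fitted extreme-value distribution of forward bit scores on random
    background sequences; ``db_size`` is the default database size used to
    convert tail probabilities to E-values.
    """

    gumbel_mu: float
    gumbel_lambda: float
    n_calibration: int
    db_size: int

    def __post_init__(self) -> None:
        if self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be > 0")


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,), shared across insert states
    transitions: dict[str, np.ndarray]
    null_model: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    calibration: Calibration | None = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.null_model = np.asarray(self.null_model, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != 20:
            raise ValueError("match_emissions must have shape (L, 20)")
        if self.L < 1:
            raise ValueError("profile must have at least one match state")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        """Check that all emission and transition rows are distributions."""
        L = self.L
        for label, arr in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions[None, :]),
            ("null model", self.null_model[None, :]),
        ):
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{label} rows must sum to 1 (got {sums})")
            if (arr < -atol).any():
                raise ValueError(f"{label} has negative entries")
        t = self.transitions
        expected_len = {
            "MM": L + 1, "MI": L + 1, "MD": L,
            "IM": L + 1, "II": L + 1, "ID": L,
            "DM": L, "DD": L - 1, "DI": L,
        }
        for key in _TRANSITION_KEYS:
            if key not in t:
                raise ValueError(f"missing transition array {key}")
            if len(t[key]) != expected_len[key]:
                raise ValueError(
                    f"transition {key} has length {len(t[key])}, "
                    f"expected {expected_len[key]}"
                )
        # row sums per source state
        for k in range(L + 1):
            row = t["MM"][k] + t["MI"][k] + (t["MD"][k] if k < L else 0.0)
            if abs(row - 1.0) > atol:
                raise ValueError(f"M_{k} transition row sums to {row}")
            row = t["IM"][k] + t["II"][k] + (t["ID"][k] if k < L else 0.0)
            if abs(row - 1.0) > atol:
                raise ValueError(f"I_{k} transition row sums to {row}")
        for k in range(1, L + 1):
            row = t["DM"][k - 1] + t["DI"][k - 1] + (t["DD"][k - 1] if k < L else 0.0)
            if abs(row - 1.0) > atol:
                raise ValueError(f"D_{k} transition row sums to {row}")

    # -- serialization ------------------------------------------------------

    def to_text(self, path: str | Path) -> None:
        """Write the profile in the package's plain-text format."""
        with open(path, "w") as fh:
            fh.write(f"PROFILE\t{self.name}\nL\t{self.L}\n")
            fh.write("NULL\t" + "\t".join(f"{p:.10g}" for p in self.null_model) + "\n")
            fh.write(
                "INSERT_EMIT\t"
                + "\t".join(f"{p:.10g}" for p in self.insert_emissions)
                + "\n"
            )
            for k in range(self.L):
                fh.write(
                    f"MATCH_EMIT\t{k + 1}\t"
                    + "\t".join(f"{p:.10g}" for p in self.match_emissions[k])
                    + "\n"
                )
            for key in _TRANSITION_KEYS:
                fh.write(
                    f"TRANS\t{key}\t"
                    + "\t".join(f"{p:.10g}" for p in self.transitions[key])
                    + "\n"
                )
            if self.calibration is not None:
                c = self.calibration
                fh.write(
                    f"CALIBRATION\t{c.gumbel_mu:.10g}\t{c.gumbel_lambda:.10g}"
                    f"\t{c.n_calibration}\t{c.db_size}\n"
                )
            fh.write("END\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "ProfileHMM":
        name = ""
        L = 0
        null = None
        insert = None
        match_rows: dict[int, np.ndarray] = {}
        trans: dict[str, np.ndarray] = {}
        calibration = None
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                tag = parts[0]
                if tag == "PROFILE":
                    name = parts[1]
                elif tag == "L":
                    L = int(parts[1])
                elif tag == "NULL":
                    null = np.array([float(x) for x in parts[1:]])
                elif tag == "INSERT_EMIT":
                    insert = np.array([float(x) for x in parts[1:]])
                elif tag == "MATCH_EMIT":
                    match_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]])
                elif tag == "TRANS":
                    trans[parts[1]] = np.array([float(x) for x in parts[2:]])
                elif tag == "CALIBRATION":
                    calibration = Calibration(
                        gumbel_mu=float(parts[1]),
                        gumbel_lambda=float(parts[2]),
                        n_calibration=int(parts[3]),
                        db_size=int(parts[4]),
                    )
                elif tag == "END":
                    break
        if null is None or insert is None or len(match_rows) != L:
            raise ValueError(f"malformed profile file {path}")
        match = np.vstack([match_rows[k + 1] for k in range(L)])
        return cls(
            name=name,
            match_emissions=match,
            insert_emissions=insert,
            transitions=trans,
            null_model=null,
            calibration=calibration,
        )


@dataclass(frozen=True)
class ScoredSequence:
    """Forward and Viterbi bit scores of one sequence against one profile."""

    sequence_id: str
    profile_name: str
    forward_bits: float
    viterbi_bits: float


# ---------------------------------------------------------------------------
# Profile construction from an alignment
# ---------------------------------------------------------------------------


def build_profile(
    family: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    gap_fraction_cutoff: float = 0.5,
    name: str = "profile",
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns whose gap fraction is strictly below ``gap_fraction_cutoff``
    become match states.  Match emissions are residue counts plus
    ``pseudocount`` times the background, normalised; transitions are
    counted from each sequence's implied state path through the match
    columns, with the same background-proportional (here uniform over the
    allowed targets) pseudocount weight.

    Parameters
    ----------
    family : sequence of (id, aligned_row)
        Alignment rows of equal length; gaps are ``-``.
    pseudocount : float
        Total pseudocount weight added to every count vector; >= 0.
    gap_fraction_cutoff : float
        Columns with gap fraction < cutoff are match columns.
    """
    if not family:
        raise ValueError("build_profile requires at least one aligned sequence")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rows = [row.upper().replace(".", GAP) for _, row in family]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows have inconsistent lengths")
    bg = np.asarray(background, dtype=float) if background is not None else UNIFORM_BACKGROUND.copy()

    n_seq = len(rows)
    gap_fraction = np.array(
        [sum(r[c] == GAP for r in rows) / n_seq for c in range(width)]
    )
    match_cols = [c for c in range(width) if gap_fraction[c] < gap_fraction_cutoff]
    L = len(match_cols)
    if L == 0:
        raise ValueError(
            "no alignment column passes the gap-fraction cutoff; cannot build profile"
        )
    is_match = np.zeros(width, dtype=bool)
    is_match[match_cols] = True
    col_to_state = {c: k + 1 for k, c in enumerate(match_cols)}

    # match emissions: counts + pseudocount * background
    emit_counts = np.zeros((L, 20))
    for r in rows:
        for c in match_cols:
            ch = r[c]
            if ch != GAP and ch in _AA_TO_IDX and ch != "X":
                emit_counts[col_to_state[c] - 1, _AA_TO_IDX[ch]] += 1.0
    match_emissions = emit_counts + pseudocount * bg
    match_emissions /= match_emissions.sum(axis=1, keepdims=True)

    # transition counts from implied state paths
    counts = {
        "MM": np.zeros(L + 1), "MI": np.zeros(L + 1), "MD": np.zeros(L),
        "IM": np.zeros(L + 1), "II": np.zeros(L + 1), "ID": np.zeros(L),
        "DM": np.zeros(L), "DD": np.zeros(L - 1) if L > 1 else np.zeros(0),
        "DI": np.zeros(L),
    }
    for r in rows:
        path: list[tuple[str, int]] = [("M", 0)]  # begin = M_0
        level = 0
        for c in range(width):
            ch = r[c]
            if is_match[c]:
                level = col_to_state[c]
                path.append(("M" if ch != GAP else "D", level))
            elif ch != GAP:
                path.append(("I", level))
        path.append(("M", L + 1))  # end = M_{L+1}
        for (s0, k0), (s1, _k1) in zip(path, path[1:]):
            key = s0 + s1
            if key in ("MM", "MI"):
                counts[key][k0] += 1.0
            elif key in ("MD", "ID"):
                counts[key][k0] += 1.0
            elif key in ("IM", "II"):
                counts[key][k0] += 1.0
            elif key in ("DM", "DI"):
                counts[key][k0 - 1] += 1.0
            elif key == "DD":
                counts[key][k0 - 1] += 1.0

    transitions = _normalise_transitions(counts, L, pseudocount)
    return ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=bg.copy(),
        transitions=transitions,
        null_model=bg.copy(),
    )


def _normalise_transitions(
    counts: dict[str, np.ndarray], L: int, pseudocount: float
) -> dict[str, np.ndarray]:
    """Normalise per-source-state transition counts with pseudocounts.

    Each source state's pseudocount mass is split uniformly over its
    allowed targets (3 in the interior, 2 at the final column where no
    further delete state exists).
    """
    t = {k: v.astype(float).copy() for k, v in counts.items()}
    for k in range(L + 1):
        n_targets = 3 if k < L else 2
        pc = pseudocount / n_targets if pseudocount > 0 else 0.0
        for key in ("MM", "MI") + (("MD",) if k < L else ()):
            t[key][k if key != "MD" else k] += pc
        total = t["MM"][k] + t["MI"][k] + (t["MD"][k] if k < L else 0.0)
        if total <= 0:  # unvisited state with zero pseudocount: uniform
            t["MM"][k] = t["MI"][k] = 1.0 / n_targets
            if k < L:
                t["MD"][k] = 1.0 / n_targets
            total = 1.0
        t["MM"][k] /= total
        t["MI"][k] /= total
        if k < L:
            t["MD"][k] /= total
        # insert state I_k
        pc_i = pseudocount / n_targets if pseudocount > 0 else 0.0
        t["IM"][k] += pc_i
        t["II"][k] += pc_i
        if k < L:
            t["ID"][k] += pc_i
        total = t["IM"][k] + t["II"][k] + (t["ID"][k] if k < L else 0.0)
        if total <= 0:
            t["IM"][k] = t["II"][k] = 1.0 / n_targets
            if k < L:
                t["ID"][k] = 1.0 / n_targets
            total = 1.0
        t["IM"][k] /= total
        t["II"][k] /= total
        if k < L:
            t["ID"][k] /= total
    for k in range(1, L + 1):
        n_targets = 3 if k < L else 2
        pc = pseudocount / n_targets if pseudocount > 0 else 0.0
        t["DM"][k - 1] += pc
        t["DI"][k - 1] += pc
        if k < L:
            t["DD"][k - 1] += pc
        total = t["DM"][k - 1] + t["DI"][k - 1] + (t["DD"][k - 1] if k < L else 0.0)
        if total <= 0:
            t["DM"][k - 1] = t["DI"][k - 1] = 1.0 / n_targets
            if k < L:
                t["DD"][k - 1] = 1.0 / n_targets
            total = 1.0
        t["DM"][k - 1] /= total
        t["DI"][k - 1] /= total
        if k < L:
            t["DD"][k - 1] /= total
    return t


# ---------------------------------------------------------------------------
# Scoring: forward and Viterbi in log-odds space
# ---------------------------------------------------------------------------


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _score_tables(profile: ProfileHMM):
    """Log-odds emission scores and log transition probabilities.

    Returns arrays suitable for the numba kernels: msc has shape (L, 21)
    with column 20 (the X residue) scored 0; isc has shape (21,).
    """
    null = profile.null_model
    msc = np.zeros((profile.L, 21))
    msc[:, :20] = _log(profile.match_emissions) - _log(null)[None, :]
    isc = np.zeros(21)
    isc[:20] = _log(profile.insert_emissions) - _log(null)
    t = profile.transitions
    logs = {k: _log(np.asarray(t[k], dtype=float)) for k in _TRANSITION_KEYS}
    return msc, isc, logs


@njit(cache=False)
def _forward_kernel(x, mo, io, MM, MI, MD, IM, II, ID, DM, DD, DI):
    """Forward log-odds over the glocal profile HMM; natural-log result.

    Runs in scaled linear space: emission tables carry odds ratios
    (emission / background), transitions are plain probabilities, and each
    row is renormalised with the log of the scale accumulated, so the DP
    costs multiply-adds instead of log-sum-exps.
    """
    n = x.shape[0]
    L = mo.shape[0]
    M = np.zeros(L + 1)
    I = np.zeros(L + 1)
    D = np.zeros(L + 1)  # D[k] for D_k, slot 0 unused
    M[0] = 1.0
    logscale = 0.0
    for i in range(n + 1):
        # delete chain within the same row (no emission)
        for k in range(1, L + 1):
            acc = M[k - 1] * MD[k - 1] + I[k - 1] * ID[k - 1]
            if k >= 2:
                acc += D[k - 1] * DD[k - 2]
            D[k] = acc
        if i == n:
            break
        c = x[i]
        newM = np.zeros(L + 1)
        newI = np.zeros(L + 1)
        for k in range(1, L + 1):
            acc = M[k - 1] * MM[k - 1] + I[k - 1] * IM[k - 1]
            if k >= 2:
                acc += D[k - 1] * DM[k - 2]
            newM[k] = acc * mo[k - 1, c]
        for k in range(L + 1):
            acc = M[k] * MI[k] + I[k] * II[k]
            if k >= 1:
                acc += D[k] * DI[k - 1]
            newI[k] = acc * io[c]
        M = newM
        I = newI
        s = 0.0
        for k in range(L + 1):
            s += M[k] + I[k]
        if s <= 0.0:
            return -np.inf
        logscale += np.log(s)
        for k in range(L + 1):
            M[k] /= s
            I[k] /= s
    end = M[L] * MM[L] + I[L] * IM[L] + D[L] * DM[L - 1]
    if end <= 0.0:
        return -np.inf
    return np.log(end) + logscale


@njit(cache=False)
def _viterbi_kernel(x, msc, isc, lMM, lMI, lMD, lIM, lII, lID, lDM, lDD, lDI):
    """Viterbi (max over paths) log-odds in log space; natural-log result."""
    n = x.shape[0]
    L = msc.shape[0]
    M = np.full(L + 1, -np.inf)
    I = np.full(L + 1, -np.inf)
    D = np.full(L + 1, -np.inf)
    M[0] = 0.0
    for i in range(n + 1):
        for k in range(1, L + 1):
            best = M[k - 1] + lMD[k - 1]
            b = I[k - 1] + lID[k - 1]
            if b > best:
                best = b
            if k >= 2:
                b = D[k - 1] + lDD[k - 2]
                if b > best:
                    best = b
            D[k] = best
        if i == n:
            break
        c = x[i]
        newM = np.full(L + 1, -np.inf)
        newI = np.full(L + 1, -np.inf)
        for k in range(1, L + 1):
            best = M[k - 1] + lMM[k - 1]
            b = I[k - 1] + lIM[k - 1]
            if b > best:
                best = b
            if k >= 2:
                b = D[k - 1] + lDM[k - 2]
                if b > best:
                    best = b
            newM[k] = best + msc[k - 1, c]
        for k in range(L + 1):
            best = M[k] + lMI[k]
            b = I[k] + lII[k]
            if b > best:
                best = b
            if k >= 1:
                b = D[k] + lDI[k - 1]
                if b > best:
                    best = b
            newI[k] = best + isc[c]
        M = newM
        I = newI
    best = M[L] + lMM[L]
    b = I[L] + lIM[L]
    if b > best:
        best = b
    b = D[L] + lDM[L - 1]
    if b > best:
        best = b
    return best


def _forward_args(profile: ProfileHMM):
    """Linear-space tables for the scaled forward kernel (cached)."""
    cached = profile.__dict__.get("_forward_args_cache")
    if cached is not None:
        return cached
    null = profile.null_model
    mo = np.ones((profile.L, 21))
    mo[:, :20] = profile.match_emissions / null[None, :]
    io = np.ones(21)
    io[:20] = profile.insert_emissions / null
    t = profile.transitions
    args = (mo, io) + tuple(
        np.ascontiguousarray(t[k], dtype=np.float64) for k in _TRANSITION_KEYS
    )
    profile.__dict__["_forward_args_cache"] = args
    return args


def _viterbi_args(profile: ProfileHMM):
    """Log-space tables for the Viterbi kernel (cached)."""
    cached = profile.__dict__.get("_viterbi_args_cache")
    if cached is not None:
        return cached
    msc, isc, logs = _score_tables(profile)
    args = (msc, isc) + tuple(logs[k] for k in _TRANSITION_KEYS)
    profile.__dict__["_viterbi_args_cache"] = args
    return args


def forward_bits(profile: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Forward bit score: log2 odds of the sequence under the profile
    versus an i.i.d. background null of the same length, summed over all
    glocal state paths."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("cannot score an empty sequence")
    x = encode_sequence(residues)
    return float(_forward_kernel(x, *_forward_args(profile))) / LN2


def viterbi_bits(profile: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Viterbi bit score: log2 odds of the single best glocal state path."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("cannot score an empty sequence")
    x = encode_sequence(residues)
    return float(_viterbi_kernel(x, *_viterbi_args(profile))) / LN2


def viterbi_alignment(
    profile: ProfileHMM, seq: SequenceRecord | str
) -> tuple[float, list[tuple[str, int]]]:
    """Viterbi bit score together with the argmax state path.

    The path is a list of (state, column) pairs over states M/I/D,
    excluding begin and end.  Implemented as a straightforward
    dynamic-programming traceback (used diagnostically; bulk scoring goes
    through :func:`viterbi_bits`).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("cannot score an empty sequence")
    x = encode_sequence(residues)
    msc, isc, logs = _score_tables(profile)
    L, n = profile.L, len(x)
    M = np.full((n + 1, L + 1), NEG_INF)
    I = np.full((n + 1, L + 1), NEG_INF)
    D = np.full((n + 1, L + 1), NEG_INF)
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    M[0, 0] = 0.0
    for i in range(n + 1):
        for k in range(1, L + 1):
            cands = [("M", i, k - 1, M[i, k - 1] + logs["MD"][k - 1]),
                     ("I", i, k - 1, I[i, k - 1] + logs["ID"][k - 1])]
            if k >= 2:
                cands.append(("D", i, k - 1, D[i, k - 1] + logs["DD"][k - 2]))
            s, ii, kk, val = max(cands, key=lambda c: c[3])
            D[i, k] = val
            ptr[("D", i, k)] = (s, ii, kk)
        if i == n:
            break
        c = x[i]
        for k in range(1, L + 1):
            cands = [("M", i, k - 1, M[i, k - 1] + logs["MM"][k - 1]),
                     ("I", i, k - 1, I[i, k - 1] + logs["IM"][k - 1])]
            if k >= 2:
                cands.append(("D", i, k - 1, D[i, k - 1] + logs["DM"][k - 2]))
            s, ii, kk, val = max(cands, key=lambda cnd: cnd[3])
            M[i + 1, k] = val + msc[k - 1, c]
            ptr[("M", i + 1, k)] = (s, ii, kk)
        for k in range(L + 1):
            cands = [("M", i, k, M[i, k] + logs["MI"][k]),
                     ("I", i, k, I[i, k] + logs["II"][k])]
            if k >= 1:
                cands.append(("D", i, k, D[i, k] + logs["DI"][k - 1]))
            s, ii, kk, val = max(cands, key=lambda cnd: cnd[3])
            I[i + 1, k] = val + isc[c]
            ptr[("I", i + 1, k)] = (s, ii, kk)
    cands = [("M", n, L, M[n, L] + logs["MM"][L]),
             ("I", n, L, I[n, L] + logs["IM"][L]),
             ("D", n, L, D[n, L] + logs["DM"][L - 1])]
    s, ii, kk, best = max(cands, key=lambda cnd: cnd[3])
    path = []
    cur = (s, ii, kk)
    while cur != ("M", 0, 0):
        st, i, k = cur
        path.append((st, k))
        cur = ptr[(st, i, k)]
    path.reverse()
    return best / LN2, path


def score_sequence(profile: ProfileHMM, seq: SequenceRecord) -> ScoredSequence:
    return ScoredSequence(
        sequence_id=seq.id,
        profile_name=profile.name,
        forward_bits=forward_bits(profile, seq),
        viterbi_bits=viterbi_bits(profile, seq),
    )


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------


def sample_background_sequence(rng: np.random.Generator, length: int,
                               background: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(AMINO_ACIDS[i] for i in idx)


def default_length_sampler(L: int) -> Callable[[np.random.Generator], int]:
    """Uniform lengths in [0.8 L, 1.2 L] (at least 1)."""

    def sampler(rng: np.random.Generator) -> int:
        lo = max(1, int(round(0.8 * L)))
        hi = max(lo, int(round(1.2 * L)))
        return int(rng.integers(lo, hi + 1))

    return sampler


def _censored_gumbel_fit(
    scores: np.ndarray, tail_fraction: float
) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit censored below the (1 - tail_fraction)
    quantile: scores above the threshold enter the likelihood exactly,
    scores below contribute only P(S < threshold).  Initialised by the
    method of moments; ``tail_fraction=1`` reduces to the plain MLE."""
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must be in (0, 1]")
    beta0 = np.std(scores) * math.sqrt(6.0) / math.pi
    mu0 = float(np.mean(scores) - np.euler_gamma * beta0)
    if tail_fraction >= 1.0:
        loc, scale = stats.gumbel_r.fit(scores, loc=mu0, scale=beta0)
        return float(loc), float(scale)
    threshold = float(np.quantile(scores, 1.0 - tail_fraction))
    tail = scores[scores >= threshold]
    n_censored = len(scores) - len(tail)

    def nll(params: np.ndarray) -> float:
        mu, log_beta = params
        beta = math.exp(log_beta)
        z = (tail - mu) / beta
        ll = float(np.sum(-log_beta - z - np.exp(-z)))
        if n_censored:
            ll += n_censored * float(stats.gumbel_r.logcdf(threshold, mu, beta))
        return -ll

    res = optimize.minimize(nll, [mu0, math.log(beta0)], method="Nelder-Mead")
    if not res.success:
        raise ValueError(f"Gumbel tail fit did not converge: {res.message}")
    return float(res.x[0]), float(math.exp(res.x[1]))


def calibrate_evalue(
    profile: ProfileHMM,
    n_random: int = 1000,
    length_sampler: Callable[[np.random.Generator], int] | None = None,
    db_size: int = 1000,
    seed: int = 0,
    tail_fraction: float = 0.25,
) -> ProfileHMM:
    """Fit the Gumbel null distribution of forward bit scores.

    Scores ``n_random`` random sequences drawn i.i.d. from the null model
    (lengths from ``length_sampler``, by default uniform within 20% of the
    profile length) and fits a Gumbel by censored maximum likelihood on the
    upper ``tail_fraction`` of the scores (method-of-moments
    initialisation).  Fitting the tail rather than the whole sample keeps
    the E-values honest where they matter: the body of the forward-score
    null is lighter-skewed than a Gumbel, and a full-sample fit
    systematically overestimates tail probabilities.  Pass
    ``tail_fraction=1.0`` for the plain full-sample MLE.  E-values are then
    ``E(S) = db_size * P_gumbel(score >= S)``.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    sampler = length_sampler or default_length_sampler(profile.L)
    scores = np.empty(n_random)
    args = _forward_args(profile)
    for i in range(n_random):
        length = sampler(rng)
        seq = sample_background_sequence(rng, length, profile.null_model)
        scores[i] = _forward_kernel(encode_sequence(seq), *args) / LN2
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate (zero-variance) null score distribution")
    loc, scale = _censored_gumbel_fit(scores, tail_fraction)
    profile.calibration = Calibration(
        gumbel_mu=float(loc),
        gumbel_lambda=float(1.0 / scale),
        n_calibration=n_random,
        db_size=db_size,
    )
    return profile


def evalue(profile: ProfileHMM, bits: float, db_size: int | None = None) -> float:
    """E-value of a bit score under the profile's Gumbel calibration."""
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    c = profile.calibration
    db = db_size if db_size is not None else c.db_size
    p = stats.gumbel_r.sf(bits, loc=c.gumbel_mu, scale=1.0 / c.gumbel_lambda)
    return float(db * p)
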
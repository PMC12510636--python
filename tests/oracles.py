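"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
scores are recomputed by exhaustive enumeration over complete state paths,
so agreement with the forward/Viterbi implementations is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np

from coconserve.profilehmm import LN2, ProfileHMM, _score_tables, encode_sequence


def enumerate_path_scores(profile: ProfileHMM, seq: str) -> np.ndarray:
    """Log-odds (natural log) of every complete glocal state path that
    emits ``seq``, by explicit recursion over the state graph."""
    msc, isc, logs = _score_tables(profile)
    L = profile.L
    x = encode_sequence(seq)
    n = len(x)
    out: list[float] = []

    def step(state: str, k: int, pos: int, logp: float) -> None:
        if not np.isfinite(logp):
            return
        if state == "M":
            options = [("M", k + 1, logs["MM"][k]), ("I", k, logs["MI"][k])]
            if k < L:
                options.append(("D", k + 1, logs["MD"][k]))
        elif state == "I":
            options = [("M", k + 1, logs["IM"][k]), ("I", k, logs["II"][k])]
            if k < L:
                options.append(("D", k + 1, logs["ID"][k]))
        else:  # D_k, 1 <= k <= L
            options = [("M", k + 1, logs["DM"][k - 1]), ("I", k, logs["DI"][k - 1])]
            if k < L:
                options.append(("D", k + 1, logs["DD"][k - 1]))
        for s2, k2, lt in options:
            if s2 == "M" and k2 == L + 1:  # end state
                if pos == n:
                    out.append(logp + lt)
            elif s2 == "M":
                if pos < n:
                    step("M", k2, pos + 1, logp + lt + msc[k2 - 1, x[pos]])
            elif s2 == "I":
                if pos < n:
                    step("I", k2, pos + 1, logp + lt + isc[x[pos]])
            else:
                step("D", k2, pos, logp + lt)

    step("M", 0, 0, 0.0)  # begin state is M_0
    return np.array(out)


def brute_force_forward_bits(profile: ProfileHMM, seq: str) -> float:
    scores = enumerate_path_scores(profile, seq)
    if scores.size == 0:
        return float("-inf")
    m = scores.max()
    return float((m + np.log(np.exp(scores - m).sum())) / LN2)


def brute_force_viterbi_bits(profile: ProfileHMM, seq: str) -> float:
    scores = enumerate_path_scores(profile, seq)
    return float(scores.max() / LN2) if scores.size else float("-inf")


def brute_force_global_alignment_identity(a: str, b: str) -> float:
    """Max identical pairs over ALL global alignments, divided by the
    shorter length.  Exhaustive recursion; only usable for tiny strings.

    Maximising identical pairs directly (rather than a substitution score)
    gives an upper bound on the identity any single optimal alignment can
    report, and equals it when the score-optimal alignment also maximises
    identities (the case for the near-identical fixtures it is used on).
    """

    def best(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        candidates = [best(i + 1, j), best(i, j + 1)]
        candidates.append((a[i] == b[j]) + best(i + 1, j + 1))
        return max(candidates)

    return best(0, 0) / min(len(a), len(b))
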
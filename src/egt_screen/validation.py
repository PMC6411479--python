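"""Brute-force reference scorers for profile HMMs.

These enumerate every legal state path explicitly and are exponential in
sequence length and model size; they exist to validate the dynamic-programming
kernels on tiny instances (M <= 4, |seq| <= 5) and deliberately share no code
with them: scores are accumulated directly from the profile's probability
parameters.
"""

from __future__ import annotations

import math

import numpy as np

from .profile_hmm import ProfileHMM, encode_sequence

__all__ = [
    "enumerate_path_scores",
    "brute_viterbi",
    "brute_forward",
    "sequence_probability",
]


def _log2(p: float) -> float:
    return math.log2(p) if p > 0 else -math.inf


def enumerate_path_scores(profile: ProfileHMM, seq: str, mode: str = "local"):
    """Log2-odds score of every legal path aligning ``seq`` to the profile."""
    enc = encode_sequence(seq)
    L, M = len(enc), profile.M

    def em_match(k: int, pos: int) -> float:
        s = enc[pos]
        if s == 20:
            return 0.0
        return _log2(profile.match_emissions[k - 1, s]) - _log2(
            profile.background[s]
        )

    def em_ins(pos: int) -> float:
        s = enc[pos]
        if s == 20:
            return 0.0
        return _log2(profile.insert_emissions[s]) - _log2(profile.background[s])

    def moves(state: str, k: int):
        if state == "M":
            return [("M", k + 1, profile.t_mm[k]),
                    ("I", k, profile.t_mi[k]),
                    ("D", k + 1, profile.t_md[k])]
        if state == "I":
            return [("M", k + 1, profile.t_im[k]),
                    ("I", k, profile.t_ii[k])]
        return [("M", k + 1, profile.t_dm[k]),
                ("D", k + 1, profile.t_dd[k])]

    scores: list[float] = []

    if mode == "glocal":
        # Node M+1 plays the role of the end state; reaching it with the whole
        # sequence consumed completes a path.
        def go(state: str, k: int, pos: int, acc: float):
            for nstate, nk, p in moves(state, k):
                if p <= 0:
                    continue
                t = _log2(p)
                if nstate == "M" and nk == M + 1:
                    if pos == L:
                        scores.append(acc + t)
                    continue
                if nk > M:
                    continue
                if nstate == "M":
                    if pos < L:
                        go("M", nk, pos + 1, acc + t + em_match(nk, pos))
                elif nstate == "I":
                    if pos < L:
                        go("I", nk, pos + 1, acc + t + em_ins(pos))
                else:
                    go("D", nk, pos, acc + t)

        go("M", 0, 0, 0.0)  # begin behaves as M_0
        return scores

    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")

    entry = -math.log2(M)
    ext = -math.log2(M)

    def go_local(state: str, k: int, pos: int, acc: float):
        if state == "M":
            # exit here: unaligned trailing residues score zero
            scores.append(acc + ext)
        for nstate, nk, p in moves(state, k):
            if p <= 0 or nk > M:
                continue
            t = _log2(p)
            if nstate == "M":
                if pos < L:
                    go_local("M", nk, pos + 1, acc + t + em_match(nk, pos))
            elif nstate == "I":
                if pos < L:
                    go_local("I", nk, pos + 1, acc + t + em_ins(pos))
            else:
                go_local("D", nk, pos, acc + t)

    for start in range(L):
        for j in range(1, M + 1):
            e = em_match(j, start)
            if e > -math.inf:
                go_local("M", j, start + 1, entry + e)
    return scores


def brute_viterbi(profile: ProfileHMM, seq: str, mode: str = "local") -> float:
    scores = enumerate_path_scores(profile, seq, mode)
    finite = [s for s in scores if s > -math.inf]
    return max(finite) if finite else -math.inf


def brute_forward(profile: ProfileHMM, seq: str, mode: str = "local") -> float:
    scores = [s for s in enumerate_path_scores(profile, seq, mode) if s > -math.inf]
    if not scores:
        return -math.inf
    m = max(scores)
    return m + math.log2(sum(2 ** (s - m) for s in scores))


def sequence_probability(profile: ProfileHMM, seq: str, score_bits: float) -> float:
    """Convert a glocal log2-odds score back to an absolute sequence
    probability under the profile's generative model."""
    if score_bits == -math.inf:
        return 0.0
    enc = encode_sequence(seq)
    null = float(np.sum(np.log2(profile.background[enc]))) if len(enc) else 0.0
    return float(2.0 ** (score_bits + null))
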
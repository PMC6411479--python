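"""Profile hidden Markov models for protein family search.

A profile is built from a reference alignment: columns whose gap fraction is
below an occupancy threshold become match states; emissions are observed
counts plus background-proportional pseudocounts; transitions are estimated
from the alignment's gap structure with Laplace smoothing.  Scoring reports
log-odds bit scores against an i.i.d. background null.  Two alignment modes
are supported: ``glocal`` (the whole model must be traversed; the model is a
proper generative distribution over sequences) and ``local`` (entry into and
exit from any match state, each weighted 1/M, with unaligned flanking
residues scored by the null) which is the search default because
transcriptome-derived proteins are frequently fragmentary.

Statistical significance uses an extreme-value (Gumbel) calibration fitted by
maximum likelihood to the local Viterbi scores of background-sampled decoy
sequences, from which E-values at any database size follow.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels
from .seqio import AMINO_ACIDS, Alignment, ProteinRecord

__all__ = [
    "ProfileHMM",
    "BACKGROUND",
    "build_profile",
    "viterbi_score",
    "forward_score",
    "calibrate",
    "evalue",
    "align_to_profile",
    "profile_to_json",
    "profile_from_json",
    "encode_sequence",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_X_INDEX = 20

# Robinson & Robinson (1991) amino-acid frequencies, the standard null for
# protein profile search, reordered to the package alphabet and renormalized.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND = np.array([_RR[a] for a in AMINO_ACIDS])
BACKGROUND /= BACKGROUND.sum()


def encode_sequence(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        out[i] = _AA_INDEX.get(c, _X_INDEX)
    return out


def _check_stochastic(vec, what, tol=1e-9):
    s = float(np.sum(vec))
    if abs(s - 1.0) > tol:
        raise ValueError(f"{what} sums to {s}, not 1")
    if np.any(np.asarray(vec) < -tol):
        raise ValueError(f"{what} has negative entries")


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with begin node 0 and implicit end node.

    Transition arrays are indexed by source node k (0..M): ``t_mm[k]`` is
    M_k -> M_{k+1} (node M: -> end), ``t_md[M]`` is structurally zero, and
    delete states terminate with ``t_dm[M] = 1``.
    """

    family: str
    M: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    match_columns: list[int] = field(default_factory=list)
    calibration: tuple[float, float] | None = None  # (mu, lambda)
    source_hash: str = ""
    _log: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("profile needs at least one match state")
        if self.match_emissions.shape != (self.M, 20):
            raise ValueError("match_emissions must be (M, 20)")
        for k in range(self.M):
            _check_stochastic(self.match_emissions[k], f"match emission {k + 1}")
        _check_stochastic(self.insert_emissions, "insert emission")
        _check_stochastic(self.background, "background")
        for k in range(self.M + 1):
            _check_stochastic(
                [self.t_mm[k], self.t_mi[k], self.t_md[k]], f"M{k} transitions"
            )
            _check_stochastic([self.t_im[k], self.t_ii[k]], f"I{k} transitions")
            if k >= 1:
                _check_stochastic([self.t_dm[k], self.t_dd[k]], f"D{k} transitions")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("calibration lambda must be positive")
        if not self.match_columns:
            self.match_columns = list(range(self.M))

    # -- cached score-space parameter views ---------------------------------

    def _tables(self):
        if "lom" not in self._log:
            with np.errstate(divide="ignore", invalid="ignore"):
                lom20 = np.log2(self.match_emissions) - np.log2(self.background)
                loi20 = np.log2(self.insert_emissions) - np.log2(self.background)
            # residues absent from both model and background are unreachable
            lom20 = np.where(np.isnan(lom20), -np.inf, lom20)
            loi20 = np.where(np.isnan(loi20), -np.inf, loi20)
            lom = np.zeros((self.M, 21))
            lom[:, :20] = lom20
            loi = np.zeros(21)
            loi[:20] = loi20
            logt = {}
            for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
                with np.errstate(divide="ignore"):
                    logt[name] = np.log2(np.asarray(getattr(self, name), float))
            self._log["lom"] = lom
            self._log["loi"] = loi
            self._log["logt"] = logt
            with np.errstate(divide="ignore", invalid="ignore"):
                pom20 = self.match_emissions / self.background
                poi20 = self.insert_emissions / self.background
            pom = np.ones((self.M, 21))
            pom[:, :20] = np.nan_to_num(pom20, nan=0.0, posinf=0.0)
            poi = np.ones(21)
            poi[:20] = np.nan_to_num(poi20, nan=0.0, posinf=0.0)
            self._log["pom"] = pom
            self._log["poi"] = poi
        return self._log


def build_profile(
    alignment: Alignment,
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray = BACKGROUND,
) -> ProfileHMM:
    """Estimate a profile from a reference alignment.

    Columns with gap fraction < ``occupancy_threshold`` become match states.
    Emissions: (counts + pseudocount_weight * background) normalized, with X
    residues ignored.  Transitions: per-row state paths through the column
    classification, counted with Laplace (+1) smoothing over each state's
    allowed moves.
    """
    if alignment.n_rows == 0:
        raise ValueError("cannot build a profile from an empty alignment")
    ncol, nrow = alignment.n_columns, alignment.n_rows
    cols = np.array([[row[1][c] for row in alignment.rows] for c in range(ncol)])
    gap_frac = (cols == "-").mean(axis=1)
    match_cols = [c for c in range(ncol) if gap_frac[c] < occupancy_threshold]
    if not match_cols:
        raise ValueError(
            "no column passes the occupancy threshold "
            f"{occupancy_threshold}; lower it or check the alignment"
        )
    M = len(match_cols)

    emis = np.tile(background * pseudocount_weight, (M, 1))
    denom = np.full(M, pseudocount_weight)
    for k, c in enumerate(match_cols):
        for ch in cols[c]:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                emis[k, idx] += 1.0
                denom[k] += 1.0
    emis /= denom[:, None]

    # transition counts with Laplace smoothing
    c_mm = np.ones(M + 1)
    c_mi = np.ones(M + 1)
    c_md = np.ones(M + 1)
    c_md[M] = 0.0  # no delete state beyond the last node
    c_im = np.ones(M + 1)
    c_ii = np.ones(M + 1)
    c_dm = np.ones(M + 1)
    c_dd = np.ones(M + 1)
    c_dd[M] = 0.0

    match_set = set(match_cols)
    for _, gapped in alignment.rows:
        prev = ("M", 0)  # begin acts as M_0
        k = 0
        for c in range(ncol):
            ch = gapped[c]
            if c in match_set:
                k += 1
                state = ("M", k) if ch != "-" else ("D", k)
            else:
                if ch == "-":
                    continue
                state = ("I", k)
            _count(prev, state, c_mm, c_mi, c_md, c_im, c_ii, c_dm, c_dd)
            prev = state
        _count(prev, ("M", M + 1), c_mm, c_mi, c_md, c_im, c_ii, c_dm, c_dd)

    t_mm = np.zeros(M + 1)
    t_mi = np.zeros(M + 1)
    t_md = np.zeros(M + 1)
    t_im = np.zeros(M + 1)
    t_ii = np.zeros(M + 1)
    t_dm = np.zeros(M + 1)
    t_dd = np.zeros(M + 1)
    for k in range(M + 1):
        tot = c_mm[k] + c_mi[k] + c_md[k]
        t_mm[k], t_mi[k], t_md[k] = c_mm[k] / tot, c_mi[k] / tot, c_md[k] / tot
        tot = c_im[k] + c_ii[k]
        t_im[k], t_ii[k] = c_im[k] / tot, c_ii[k] / tot
        tot = c_dm[k] + c_dd[k]
        t_dm[k], t_dd[k] = c_dm[k] / tot, c_dd[k] / tot

    digest = hashlib.blake2b(
        "".join(f">{r.id}\n{g}\n" for r, g in alignment.rows).encode(),
        digest_size=8,
    ).hexdigest()
    return ProfileHMM(
        family=alignment.family,
        M=M,
        match_emissions=emis,
        insert_emissions=background.copy(),
        background=background.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        match_columns=match_cols,
        source_hash=digest,
    )


def _count(prev, state, c_mm, c_mi, c_md, c_im, c_ii, c_dm, c_dd):
    ps, pk = prev
    s, k = state
    if ps == "M":
        if s == "M":
            c_mm[pk] += 1
        elif s == "I":
            c_mi[pk] += 1
        else:
            c_md[pk] += 1
    elif ps == "I":
        if s == "I":
            c_ii[pk] += 1
        else:
            c_im[pk] += 1
    else:  # D
        if s == "D":
            c_dd[pk] += 1
        else:
            c_dm[pk] += 1


# --------------------------------------------------------------------------
# scoring


def _mode_flag(mode: str) -> bool:
    if mode not in ("local", "glocal"):
        raise ValueError(f"mode must be 'local' or 'glocal', got {mode!r}")
    return mode == "local"


def viterbi_bits(profile: ProfileHMM, seq: str, mode: str = "local") -> float:
    """Best-path log-odds score in bits (no traceback; fast path)."""
    t = profile._tables()
    lt = t["logt"]
    _, _, _, best = _kernels.viterbi_fill(
        t["lom"], t["loi"],
        lt["t_mm"], lt["t_mi"], lt["t_md"], lt["t_im"], lt["t_ii"],
        lt["t_dm"], lt["t_dd"],
        encode_sequence(seq), _mode_flag(mode),
    )
    return float(best)


def viterbi_score(profile: ProfileHMM, seq: str, mode: str = "local"):
    """Best path score with traceback.

    Returns (bits, path, interval): path is a list of (state, node, seq_index)
    triples with seq_index None for delete states; interval is the 0-based
    half-open aligned span on the sequence (the full sequence in glocal mode).
    """
    local = _mode_flag(mode)
    t = profile._tables()
    lt = t["logt"]
    enc = encode_sequence(seq)
    VM, VI, VD, best = _kernels.viterbi_fill(
        t["lom"], t["loi"],
        lt["t_mm"], lt["t_mi"], lt["t_md"], lt["t_im"], lt["t_ii"],
        lt["t_dm"], lt["t_dd"],
        enc, local,
    )
    if not np.isfinite(best):
        return float(best), [], (0, 0)
    path = _traceback(profile, enc, VM, VI, VD, best, local, t, lt)
    emitted = [i for (_, _, i) in path if i is not None]
    interval = (min(emitted), max(emitted) + 1) if emitted else (0, 0)
    return float(best), path, interval


def _traceback(profile, enc, VM, VI, VD, best, local, t, lt):
    M = profile.M
    L = enc.shape[0]
    lom, loi = t["lom"], t["loi"]
    tol = 1e-6
    if local:
        flat = np.argmax(VM)
        r, k = int(flat // (M + 1)), int(flat % (M + 1))
        state = "M"
    else:
        cands = [
            ("M", VM[L, M] + lt["t_mm"][M]),
            ("I", VI[L, M] + lt["t_im"][M]),
            ("D", VD[L, M] + lt["t_dm"][M]),
        ]
        state = max(cands, key=lambda x: x[1])[0]
        r, k = L, M
    path = []
    entry = -np.log2(M) if local else None
    while True:
        if state == "M":
            if k == 0:
                break  # begin
            path.append(("M", k, r - 1))
            val = VM[r, k] - lom[k - 1, enc[r - 1]]
            if local and abs(val - entry) < tol:
                break
            opts = [
                ("M", VM[r - 1, k - 1] + lt["t_mm"][k - 1]),
                ("I", VI[r - 1, k - 1] + lt["t_im"][k - 1]),
                ("D", VD[r - 1, k - 1] + lt["t_dm"][k - 1]),
            ]
            state = _pick(opts, val, tol)
            r, k = r - 1, k - 1
            if state == "M" and k == 0 and r == 0:
                break
        elif state == "I":
            path.append(("I", k, r - 1))
            val = VI[r, k] - loi[enc[r - 1]]
            opts = [
                ("M", VM[r - 1, k] + lt["t_mi"][k]),
                ("I", VI[r - 1, k] + lt["t_ii"][k]),
            ]
            state = _pick(opts, val, tol)
            r = r - 1
            if state == "M" and k == 0 and r == 0:
                break
        else:  # D
            path.append(("D", k, None))
            val = VD[r, k]
            opts = [
                ("M", VM[r, k - 1] + lt["t_md"][k - 1]),
                ("D", VD[r, k - 1] + lt["t_dd"][k - 1]),
            ]
            state = _pick(opts, val, tol)
            k = k - 1
            if state == "M" and k == 0 and r == 0:
                break
    path.reverse()
    return path


def _pick(opts, val, tol):
    for name, v in opts:
        if abs(v - val) < tol:
            return name
    # numerical fallback: nearest
    return min(opts, key=lambda x: abs(x[1] - val))[0]


def forward_score(profile: ProfileHMM, seq: str, mode: str = "local") -> float:
    """Log-sum-over-paths log-odds score in bits; always >= the Viterbi
    score on the same input."""
    local = _mode_flag(mode)
    t = profile._tables()
    score = _kernels.forward_score_kernel(
        t["pom"], t["poi"],
        np.asarray(profile.t_mm, float), np.asarray(profile.t_mi, float),
        np.asarray(profile.t_md, float), np.asarray(profile.t_im, float),
        np.asarray(profile.t_ii, float), np.asarray(profile.t_dm, float),
        np.asarray(profile.t_dd, float),
        encode_sequence(seq), local,
    )
    return float(score)


# --------------------------------------------------------------------------
# calibration and significance


def calibrate(
    profile: ProfileHMM,
    n_decoys: int = 200,
    decoy_length: int = 350,
    seed: int = 0,
) -> ProfileHMM:
    """Fit Gumbel (mu, lambda) to local Viterbi scores of i.i.d. background
    decoys and store it on the profile (returned for chaining)."""
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys for a stable Gumbel fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    t = profile._tables()
    lt = t["logt"]
    for i in range(n_decoys):
        enc = rng.choice(20, size=decoy_length, p=profile.background)
        _, _, _, best = _kernels.viterbi_fill(
            t["lom"], t["loi"],
            lt["t_mm"], lt["t_mi"], lt["t_md"], lt["t_im"], lt["t_ii"],
            lt["t_dm"], lt["t_dd"],
            enc.astype(np.int64), True,
        )
        scores[i] = best
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate decoy scores; cannot fit a Gumbel")
    loc, scale = stats.gumbel_r.fit(scores)
    profile.calibration = (float(loc), float(1.0 / scale))
    return profile


def evalue(profile: ProfileHMM, bit_score: float, database_size: int) -> float:
    """Expected number of decoys at or above ``bit_score`` in a database of
    the given size, under the profile's Gumbel calibration."""
    if profile.calibration is None:
        raise ValueError(
            f"profile {profile.family!r} is not calibrated; run calibrate() first"
        )
    mu, lam = profile.calibration
    tail = -np.expm1(-np.exp(-lam * (bit_score - mu)))
    return float(database_size * tail)


def score_at_evalue(profile: ProfileHMM, e_value: float, database_size: int) -> float:
    """Inverse of :func:`evalue`: the bit score whose E-value equals
    ``e_value`` at the given database size."""
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    mu, lam = profile.calibration
    p = min(e_value / database_size, 1.0 - 1e-12)
    return float(mu - np.log(-np.log1p(-p)) / lam)


def ungapped_filter_bits(profile: ProfileHMM, seq: str) -> float:
    """Fast match-only local score (lower bound on the local Viterbi bits);
    see :func:`_kernels.ungapped_filter_kernel`."""
    t = profile._tables()
    return float(_kernels.ungapped_filter_kernel(
        t["lom"], t["logt"]["t_mm"], encode_sequence(seq)
    ))


# --------------------------------------------------------------------------
# alignment augmentation


def profile_path(profile: ProfileHMM, seq: str):
    """Glocal alignment of a sequence to the profile, reduced to per-match
    assignments.  Returns (match_row, inserts): match_row is a list of length
    M with the residue aligned to each match state or '-'; inserts maps node
    k (0..M) to the residue run assigned to I_k."""
    _, path, _ = viterbi_score(profile, seq, mode="glocal")
    match_row = ["-"] * profile.M
    inserts: dict[int, str] = {}
    for state, k, i in path:
        if state == "M":
            match_row[k - 1] = seq[i]
        elif state == "I":
            inserts[k] = inserts.get(k, "") + seq[i]
    return match_row, inserts


def align_to_profile(
    profile: ProfileHMM, record: ProteinRecord, alignment: Alignment
) -> Alignment:
    """Insert one sequence into the profile's source alignment.

    Match-state residues land in their original columns; insert-state runs
    open dedicated new columns (gaps in every pre-existing row), so removing
    the row recovers the original column set in order.
    """
    return _merge_rows(profile, alignment, [(record, *profile_path(profile, record.sequence))])


def _merge_rows(profile, alignment, placed) -> Alignment:
    """placed: list of (record, match_row, inserts)."""
    ncol = alignment.n_columns
    col_of_match = profile.match_columns
    # width of the insert block after each anchor position; anchor -1 = before
    # the first column
    ins_width: dict[int, int] = {}
    for _, _, inserts in placed:
        for k, run in inserts.items():
            anchor = col_of_match[k - 1] if k >= 1 else -1
            ins_width[anchor] = max(ins_width.get(anchor, 0), len(run))

    def expand_existing(gapped: str) -> str:
        out = []
        if -1 in ins_width:
            out.append("-" * ins_width[-1])
        for c in range(ncol):
            out.append(gapped[c])
            if c in ins_width:
                out.append("-" * ins_width[c])
        return "".join(out)

    new_rows = [(rec, expand_existing(g)) for rec, g in alignment.rows]
    match_col_set = {c: k for k, c in enumerate(col_of_match)}
    for rec, match_row, inserts in placed:
        out = []
        if -1 in ins_width:
            run = inserts.get(0, "")
            out.append(run.ljust(ins_width[-1], "-"))
        for c in range(ncol):
            if c in match_col_set:
                out.append(match_row[match_col_set[c]])
            else:
                out.append("-")
            if c in ins_width:
                k = match_col_set.get(c)
                run = inserts.get(k + 1, "") if k is not None else ""
                out.append(run.ljust(ins_width[c], "-"))
        new_rows.append((rec, "".join(out)))
    return Alignment(alignment.family, new_rows)


# --------------------------------------------------------------------------
# serialization


def profile_to_json(profile: ProfileHMM) -> str:
    data = {
        "family": profile.family,
        "M": profile.M,
        "match_emissions": profile.match_emissions.tolist(),
        "insert_emissions": profile.insert_emissions.tolist(),
        "background": profile.background.tolist(),
        "transitions": {
            name: np.asarray(getattr(profile, name)).tolist()
            for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        },
        "match_columns": profile.match_columns,
        "calibration": profile.calibration,
        "source_hash": profile.source_hash,
    }
    return json.dumps(data)


def profile_from_json(text: str) -> ProfileHMM:
    data = json.loads(text)
    tr = {k: np.array(v) for k, v in data["transitions"].items()}
    return ProfileHMM(
        family=data["family"],
        M=data["M"],
        match_emissions=np.array(data["match_emissions"]),
        insert_emissions=np.array(data["insert_emissions"]),
        background=np.array(data["background"]),
        match_columns=list(data["match_columns"]),
        calibration=tuple(data["calibration"]) if data["calibration"] else None,
        source_hash=data.get("source_hash", ""),
        **tr,
    )
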
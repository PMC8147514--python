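"""Profile hidden Markov models of transposase catalytic domains.

A :class:`ProfileHMM` holds match/insert emissions and node transitions for
one catalytic-domain family, plus two calibrations: a Gumbel (lambda, tau)
pair for E-values and a per-model noise cutoff (NC) — the bit score of the
highest-scoring known false positive observed on a curated decoy proteome.

The search engine is a local max-path (Viterbi) dynamic programme over the
standard match/insert/delete topology; a local path may enter and leave the
model at any match state at zero cost, so it aligns a subsequence of the
target to a submodel. Bit scores are emission log-odds against the model
background plus log2 transition probabilities. Multiple domains per target
are found by masking each reported span and re-searching.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from ._kernels import NEG_INF, viterbi_local

__all__ = [
    "AMINO",
    "ProfileHMM",
    "DomainHit",
    "read_hmm",
    "write_hmm",
    "build_from_msa",
    "viterbi_domain_search",
    "calibrate_evalue",
    "score_to_evalue",
    "calibrate_noise_cutoff",
]

AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: transition order within a node, as in HMMER3 files
TRANS_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")
_GROUPS = ((0, 1, 2), (3, 4), (5, 6))  # normalisation groups M->, I->, D->


@dataclass
class DomainHit:
    """One catalytic-domain occurrence on a (translated) target."""

    model: str
    target_id: str
    frame: int
    aa_start: int
    aa_end: int
    bit_score: float
    evalue: float = math.inf

    def __post_init__(self) -> None:
        if self.aa_start >= self.aa_end:
            raise ValueError("empty domain span")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class ProfileHMM:
    """Profile HMM for one catalytic-domain family.

    ``trans[j]`` holds the seven transition probabilities out of node j in
    HMMER order (M->M, M->I, M->D, I->M, I->I, D->M, D->D); row 0 feeds
    node 1. Emissions are stored as probabilities; log-odds against
    ``background`` (bits) are derived on demand and cached.
    """

    name: str
    match_p: np.ndarray  # (M+1, K), row 0 unused
    insert_p: np.ndarray  # (M+1, K)
    trans: np.ndarray  # (M+1, 7)
    background: np.ndarray  # (K,)
    alphabet: str = AMINO
    lambda_: float | None = None
    tau: float | None = None
    noise_cutoff: float | None = None
    n_train: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def M(self) -> int:
        return self.match_p.shape[0] - 1

    @property
    def K(self) -> int:
        return len(self.alphabet)

    @property
    def calibrated(self) -> bool:
        return self.lambda_ is not None and self.tau is not None

    @property
    def entry_score(self) -> float:
        """log2 of the uniform local-entry probability 2/(M(M+1)), charged
        once per domain. Without it, every isolated well-matching residue
        would score positively and the domain search would drown in
        one-residue hits."""
        return math.log2(2.0 / (self.M * (self.M + 1)))

    def validate(self) -> None:
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: background does not sum to 1")
        for j in range(self.M + 1):
            for grp in _GROUPS:
                s = self.trans[j, list(grp)].sum()
                # D-group of node 0 and terminal rows may be deliberately void
                if s > 0 and not math.isclose(s, 1.0, abs_tol=1e-9):
                    raise ValueError(
                        f"{self.name}: node {j} transition group {grp} sums to {s}"
                    )
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValueError(f"{self.name}: lambda must be positive")
        if self.noise_cutoff is not None and self.noise_cutoff < 0:
            raise ValueError(f"{self.name}: NC must be >= 0")

    def _scores(self):
        """Log-odds emission matrices (bits) and log2 transitions for the
        DP kernel."""
        if "scores" not in self._cache:
            with np.errstate(divide="ignore"):
                mlo = np.where(
                    self.match_p > 0,
                    np.log2(np.maximum(self.match_p, 1e-300) / self.background),
                    NEG_INF,
                )
                ilo = np.where(
                    self.insert_p > 0,
                    np.log2(np.maximum(self.insert_p, 1e-300) / self.background),
                    NEG_INF,
                )
                lt = np.where(self.trans > 0, np.log2(np.maximum(self.trans, 1e-300)), NEG_INF)
            mlo[0, :] = NEG_INF
            self._cache["scores"] = (
                np.ascontiguousarray(mlo),
                np.ascontiguousarray(ilo),
                np.ascontiguousarray(lt),
            )
        return self._cache["scores"]

    def encode(self, seq: str) -> np.ndarray:
        """Map residues to alphabet indices; anything outside the alphabet
        ('*', 'X', ...) becomes -1 and cannot be emitted."""
        if "codes" not in self._cache:
            codes = np.full(128, -1, np.int64)
            for i, c in enumerate(self.alphabet):
                codes[ord(c)] = i
            self._cache["codes"] = codes
        arr = np.frombuffer(seq.encode("ascii"), np.uint8).astype(np.int64)
        return self._cache["codes"][arr]


# ---------------------------------------------------------------------------
# HMMER3-dialect text IO


def _prob_tokens(values: np.ndarray) -> str:
    out = []
    for p in values:
        out.append("*" if p <= 0 else f"{-math.log(p):.5f}")
    return "  ".join(out)


def write_hmm(models: list[ProfileHMM], path) -> None:
    """Write models in HMMER3-dialect text (emissions and transitions as
    negative natural logs of probabilities, '*' for probability zero).
    Calibration is carried on STATS LOCAL VITERBI (mu then lambda, HMMER
    order) and NC lines."""
    with open(path, "w") as fh:
        for m in models:
            fh.write("HMMER3/f [isdetect]\n")
            fh.write(f"NAME  {m.name}\n")
            fh.write(f"LENG  {m.M}\n")
            fh.write(f"ALPH  {'amino' if m.alphabet == AMINO else m.alphabet}\n")
            fh.write(f"NSEQ  {m.n_train}\n")
            if m.calibrated:
                # one score type internally; the MSV/FORWARD lines repeat
                # the Viterbi fit so standard HMMER3 readers accept the file
                fh.write(f"STATS LOCAL MSV      {m.tau:.5f}  {m.lambda_:.5f}\n")
                fh.write(f"STATS LOCAL VITERBI  {m.tau:.5f}  {m.lambda_:.5f}\n")
                fh.write(f"STATS LOCAL FORWARD  {m.tau:.5f}  {m.lambda_:.5f}\n")
            if m.noise_cutoff is not None:
                fh.write(f"NC    {m.noise_cutoff:.2f} {m.noise_cutoff:.2f};\n")
            fh.write("HMM          " + "   ".join(m.alphabet) + "\n")
            fh.write("            " + "  ".join(TRANS_ORDER) + "\n")
            fh.write(f"  COMPO  {_prob_tokens(m.background)}\n")
            fh.write(f"         {_prob_tokens(m.insert_p[0])}\n")
            fh.write(f"         {_prob_tokens(np.asarray(m.trans[0]))}\n")
            for j in range(1, m.M + 1):
                # trailing MAP/CONS/RF/MM/CS annotation columns
                fh.write(f"  {j:5d}  {_prob_tokens(m.match_p[j])}  {j} - - - -\n")
                fh.write(f"         {_prob_tokens(m.insert_p[j])}\n")
                fh.write(f"         {_prob_tokens(np.asarray(m.trans[j]))}\n")
            fh.write("//\n")


def _parse_prob_line(tokens: list[str]) -> np.ndarray:
    return np.array([0.0 if t == "*" else math.exp(-float(t)) for t in tokens])


def read_hmm(path) -> list[ProfileHMM]:
    """Read one or more profiles from an HMMER3-dialect text file.

    Emission/transition fields are negative natural logs of probabilities
    with '*' meaning probability zero. ``STATS LOCAL VITERBI`` lines (mu
    then lambda) populate the Gumbel calibration; an ``NC`` line populates
    the noise cutoff. When the file carries no explicit background, a
    uniform background over the alphabet is assumed.
    """
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].startswith("HMMER3"):
            i += 1
            continue
        header: dict[str, str] = {}
        stats = None
        nc = None
        i += 1
        while i < n and not lines[i].startswith("HMM "):
            parts = lines[i].split(None, 1)
            if parts:
                key = parts[0]
                val = parts[1] if len(parts) > 1 else ""
                if key == "STATS":
                    toks = val.split()
                    if len(toks) >= 4 and toks[1] == "VITERBI":
                        stats = (float(toks[3]), float(toks[2]))  # (lambda, tau)
                elif key == "NC":
                    nc = float(val.split()[0].rstrip(";"))
                else:
                    header[key] = val
            i += 1
        if i >= n:
            raise ValueError(f"{path}: truncated profile (missing HMM section)")
        alph_field = header.get("ALPH", "amino")
        if alph_field == "amino":
            alphabet = AMINO
        elif re.fullmatch(r"[A-Z]+", alph_field) and len(alph_field) > 1:
            alphabet = alph_field  # dialect extension: explicit alphabet
        else:
            raise ValueError(f"{path}: unsupported alphabet {alph_field!r}")
        if "LENG" not in header or "NAME" not in header:
            raise ValueError(f"{path}: missing mandatory NAME/LENG fields")
        M = int(header["LENG"])
        K = len(alphabet)
        i += 2  # skip the HMM residue header and the transition-order line
        if i < n and lines[i].split()[:1] == ["COMPO"]:
            background = _parse_prob_line(lines[i].split()[1 : K + 1])
            i += 1
        else:
            background = np.full(K, 1.0 / K)
        match_p = np.zeros((M + 1, K))
        insert_p = np.zeros((M + 1, K))
        trans = np.zeros((M + 1, 7))
        insert_p[0] = _parse_prob_line(lines[i].split()[:K])
        trans[0] = _parse_prob_line(lines[i + 1].split()[:7])
        i += 2
        for j in range(1, M + 1):
            toks = lines[i].split()
            if not toks or toks[0] != str(j):
                raise ValueError(f"{path}: expected node {j}, got {lines[i]!r}")
            match_p[j] = _parse_prob_line(toks[1 : K + 1])
            insert_p[j] = _parse_prob_line(lines[i + 1].split()[:K])
            trans[j] = _parse_prob_line(lines[i + 2].split()[:7])
            i += 3
        if i >= n or lines[i].strip() != "//":
            raise ValueError(f"{path}: profile {header['NAME']} not terminated by //")
        i += 1
        # text probabilities are rounded; renormalise to restore exact
        # group/row sums
        for row in range(1, M + 1):
            if match_p[row].sum() > 0:
                match_p[row] /= match_p[row].sum()
        for row in range(M + 1):
            if insert_p[row].sum() > 0:
                insert_p[row] /= insert_p[row].sum()
            for grp in _GROUPS:
                g = list(grp)
                s = trans[row, g].sum()
                if s > 0:
                    trans[row, g] /= s
        model = ProfileHMM(
            name=header["NAME"],
            match_p=match_p,
            insert_p=insert_p,
            trans=trans,
            background=background / background.sum(),
            alphabet=alphabet,
            lambda_=stats[0] if stats else None,
            tau=stats[1] if stats else None,
            noise_cutoff=nc,
            n_train=int(header.get("NSEQ", 0)),
        )
        model.validate()
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Building from an MSA


def _blosum_conditional(alphabet: str = AMINO) -> np.ndarray:
    """P(a | b) derived from BLOSUM62 half-bit scores against a uniform
    background, used as emission pseudocounts for single-sequence profiles."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    K = len(alphabet)
    cond = np.zeros((K, K))
    for b in range(K):
        for a in range(K):
            cond[b, a] = 2.0 ** (blosum[alphabet[b], alphabet[a]] / 2.0)
        cond[b] /= cond[b].sum()
    return cond


def build_from_msa(
    msa: list[str],
    name: str,
    min_train: int = 10,
    alphabet: str = AMINO,
    match_frac: float = 0.5,
) -> ProfileHMM:
    """Construct a profile from an aligned protein family.

    Columns in which more than ``match_frac`` of rows carry a residue
    become match states. Match emissions are residue counts with a Laplace
    pseudocount of 1; transitions are counted from each row's implied state
    path with a pseudocount of 1 per transition type; the background is
    uniform. Families must contribute at least ``min_train`` sequences so
    the model generalises to distant members; single outlier sequences are
    admitted with ``min_train=1`` and then receive BLOSUM62-derived
    emission pseudocounts instead of flat ones.
    """
    if len(msa) < min_train:
        raise ValueError(
            f"{name}: {len(msa)} aligned sequences, but profiles must be "
            f"assembled from at least {min_train} sequences"
        )
    width = len(msa[0])
    if width == 0 or any(len(row) != width for row in msa):
        raise ValueError(f"{name}: alignment rows must share one nonzero length")
    K = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    gaps = set(".-")
    rows = [row.upper() for row in msa]
    is_match = [
        sum(1 for row in rows if row[c] not in gaps) > match_frac * len(rows)
        for c in range(width)
    ]
    M = sum(is_match)
    if M == 0:
        raise ValueError(f"{name}: no match columns")
    match_counts = np.zeros((M + 1, K))
    insert_counts = np.zeros((M + 1, K))
    trans_counts = np.ones((M + 1, 7))
    for row in rows:
        node = 0  # last match/delete node passed
        prev = "m"  # state at that node ('m' covers the begin state)
        for c in range(width):
            ch = row[c]
            emitted = ch not in gaps
            if is_match[c]:
                node += 1
                state = "m" if emitted else "d"
                trans_counts[node - 1, TRANS_ORDER.index(prev + state)] += 1
                if emitted:
                    if ch in idx:
                        match_counts[node, idx[ch]] += 1
                prev = state
            elif emitted:
                trans_counts[node, TRANS_ORDER.index(prev + "i")] += 1
                if ch in idx:
                    insert_counts[node, idx[ch]] += 1
                prev = "i"
        trans_counts[node, TRANS_ORDER.index(prev + "m")] += 1  # exit as ->M
    if len(rows) == 1:
        cond = _blosum_conditional(alphabet) if alphabet == AMINO else None
        if cond is not None:
            # soft counts: 5 pseudo-observations drawn from P(.|observed)
            pseudo = np.zeros_like(match_counts)
            for j in range(1, M + 1):
                obs = match_counts[j].argmax()
                pseudo[j] = 5.0 * cond[obs]
            match_p = match_counts + pseudo
        else:
            match_p = match_counts + 1.0
    else:
        match_p = match_counts + 1.0
    match_p[1:] /= match_p[1:].sum(axis=1, keepdims=True)
    insert_p = insert_counts + 1.0
    insert_p /= insert_p.sum(axis=1, keepdims=True)
    trans = np.zeros_like(trans_counts)
    for grp in _GROUPS:
        g = list(grp)
        trans[:, g] = trans_counts[:, g] / trans_counts[:, g].sum(axis=1, keepdims=True)
    model = ProfileHMM(
        name=name,
        match_p=match_p,
        insert_p=insert_p,
        trans=trans,
        background=np.full(K, 1.0 / K),
        alphabet=alphabet,
        n_train=len(rows),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Search and calibration


def viterbi_domain_search(
    model: ProfileHMM,
    target: str,
    report_floor: float = 0.0,
    target_id: str = "",
    frame: int = 1,
    Z: int = 1,
) -> list[DomainHit]:
    """All non-overlapping local domain hits scoring at least
    ``report_floor`` bits, best first.

    The best-scoring span is reported, masked on the target, and the
    search repeated until the best remaining score drops below the floor.
    '*' (and any symbol outside the model alphabet) cannot be emitted, so
    domains never cross in-frame stop codons.
    """
    if not target:
        return []
    mlo, ilo, lt = model._scores()
    obs = model.encode(target)
    entry = model.entry_score
    hits: list[DomainHit] = []
    # masking a reported span forbids any later path from crossing it, so
    # the masked re-search decomposes exactly into the two flanking
    # segments; recursing on segments gives the same hit set faster
    segments = [(0, len(obs))]
    while segments:
        lo, hi = segments.pop()
        if hi - lo < 1:
            continue
        score, ts, te, _, _ = viterbi_local(obs[lo:hi], mlo, ilo, lt, entry)
        if score < report_floor or score <= NEG_INF / 2 or te <= ts:
            continue
        ev = score_to_evalue(model, score, Z) if model.calibrated else math.inf
        hits.append(
            DomainHit(model.name, target_id, frame, lo + ts, lo + te, float(score), ev)
        )
        segments.append((lo, lo + ts))
        segments.append((lo + te, hi))
    hits.sort(key=lambda h: (-h.bit_score, h.aa_start))
    return hits


def best_score(model: ProfileHMM, target: str) -> float:
    """Best local bit score of the model on a target (may be negative)."""
    mlo, ilo, lt = model._scores()
    score, *_ = viterbi_local(model.encode(target), mlo, ilo, lt, model.entry_score)
    return float(score)


def calibrate_evalue(
    model: ProfileHMM, n_random: int = 200, len_random: int = 200, rng_seed: int = 0
) -> tuple[float, float]:
    """Fit a Gumbel law to best scores on i.i.d. background sequences.

    Maximum-likelihood fit of location/scale; returns and stores
    (lambda, tau) with lambda = 1/scale, tau = location, both in bits.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable fit")
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(model.alphabet))
    scores = np.empty(n_random)
    for r in range(n_random):
        seq = "".join(rng.choice(letters, size=len_random, p=model.background))
        scores[r] = best_score(model, seq)
    if np.ptp(scores) < 1e-12:
        raise ValueError(f"{model.name}: degenerate score distribution, cannot fit")
    loc, scale = gumbel_r.fit(scores)
    model.lambda_ = 1.0 / scale
    model.tau = loc
    return model.lambda_, model.tau


def score_to_evalue(model: ProfileHMM, bit_score: float, Z: int = 1) -> float:
    """Expected number of hits at or above ``bit_score`` in ``Z`` searched
    sequences: E = Z * P(Gumbel >= s)."""
    if not model.calibrated:
        raise ValueError(f"{model.name}: model is not E-value calibrated")
    p = -math.expm1(-math.exp(-model.lambda_ * (bit_score - model.tau)))
    return Z * p


def calibrate_noise_cutoff(model: ProfileHMM, decoys) -> float:
    """Noise cutoff: the bit score of the highest-scoring false positive
    when the model is queried against a decoy proteome known to contain no
    true family members. 0.0 when no decoy reaches a non-negative score."""
    decoys = list(decoys)
    if not decoys:
        raise ValueError("noise-cutoff calibration needs a non-empty decoy set")
    nc = 0.0
    for rec in decoys:
        for hit in viterbi_domain_search(model, rec.seq, 0.0, rec.id):
            nc = max(nc, hit.bit_score)
    model.noise_cutoff = nc
    return nc
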
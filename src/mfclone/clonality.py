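"""Pairwise clonality testing from shared somatic variants.

Two biopsies from the same clone share "trunk" variants acquired before
dissemination.  Because recurrent hotspot mutations also co-occur by chance
in unrelated tumors, sharing is weighted by rarity: a variant carried by
few patients in the cohort is strong evidence of common origin, a frequent
one is weak.  The statistic is a frequency-weighted cosine overlap

    S(A, B) = sum_{v in A&B} w(v) / sqrt(sum_{v in A} w(v) * sum_{v in B} w(v)),

with w(v) = -log10(max(freq(v), f_min)), compared against a permutation
null in which variant sets of the observed sizes are redrawn from the
cohort variant pool with probability proportional to variant frequency
(without replacement within a replicate).  The permutation p-value uses the
add-one rule p = (1 + #{S_perm >= S_obs}) / (n_perm + 1), and a pair is
called clonal iff p <= alpha (default 0.05, boundary inclusive).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import Cohort
from .types import MutationProfile

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 999

SCOPE_INTRA = "intra_patient_inter_nodule"
SCOPE_INTER = "inter_patient"


@dataclass(frozen=True)
class PairKey:
    """Canonical (sorted) identifier of a biopsy pair."""

    biopsy_a: str
    biopsy_b: str
    scope: str = SCOPE_INTRA

    def __post_init__(self):
        if self.biopsy_a >= self.biopsy_b:
            raise ValueError(
                f"PairKey requires biopsy_a < biopsy_b; use PairKey.make() "
                f"({self.biopsy_a!r}, {self.biopsy_b!r})"
            )

    @classmethod
    def make(cls, a: str, b: str, scope: str = SCOPE_INTRA) -> "PairKey":
        if a == b:
            raise ValueError(f"a pair needs two distinct biopsies, got {a!r} twice")
        return cls(min(a, b), max(a, b), scope)


@dataclass(frozen=True)
class ClonalityResult:
    pair: PairKey
    score: float
    p_value: float
    n_perm: int
    call: str  # "clonal" | "non_clonal"
    seed: int
    n_shared: int = 0


class VariantPool:
    """The cohort variant pool: keys, frequencies, rarity weights.

    Null variant sets are drawn from this pool with probability
    proportional to frequency.  Weights floor the frequency at ``f_min`` so
    no variant carries infinite weight.
    """

    def __init__(self, freq: Mapping[str, float], f_min: float):
        if f_min <= 0:
            raise ValueError("f_min must be positive")
        self.keys = np.array(sorted(freq), dtype=object)
        self.freq = np.array([freq[k] for k in self.keys], dtype=float)
        if len(self.keys) and ((self.freq <= 0) | (self.freq > 1)).any():
            raise ValueError("pool frequencies must lie in (0, 1]")
        self.f_min = float(f_min)
        self.weights = -np.log10(np.maximum(self.freq, f_min))
        self.index = {k: i for i, k in enumerate(self.keys)}
        total = self.freq.sum()
        self._cum = np.cumsum(self.freq / total) if total > 0 else np.array([])
        if len(self._cum):
            self._cum[-1] = 1.0

    def __len__(self) -> int:
        return len(self.keys)

    def weight_of(self, key: str) -> float:
        i = self.index.get(key)
        if i is None:
            # variant absent from pool: maximally rare
            return -np.log10(self.f_min)
        return float(self.weights[i])

    @classmethod
    def from_profiles(cls, profiles: Iterable[MutationProfile], f_min: Optional[float] = None):
        freq: Dict[str, float] = {}
        for p in profiles:
            freq.update(p.cohort_freq)
        if f_min is None:
            f_min = min(freq.values()) if freq else 0.5
        return cls(freq, f_min)

    def sample_sets(self, rng: np.random.Generator, size: int, n_draws: int) -> np.ndarray:
        """Draw ``n_draws`` frequency-proportional variant-index sets of
        ``size`` without replacement (sequential conditional draws)."""
        if size > len(self):
            raise ValueError(f"cannot draw {size} variants from a pool of {len(self)}")
        out = np.empty((n_draws, size), dtype=np.int64)
        for j in range(size):
            idx = np.searchsorted(self._cum, rng.random(n_draws), side="right")
            if j:
                # redraw any index already present in its row: this is exactly
                # a draw from the renormalized distribution on remaining variants
                while True:
                    bad = (out[:, :j] == idx[:, None]).any(axis=1)
                    n_bad = int(bad.sum())
                    if not n_bad:
                        break
                    idx[bad] = np.searchsorted(self._cum, rng.random(n_bad), side="right")
            out[:, j] = idx
        return out


def _profile_weights(profile: MutationProfile, pool: VariantPool) -> float:
    return sum(pool.weight_of(k) for k in profile.variant_keys)


def clonality_score(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    pool: VariantPool,
) -> float:
    """Frequency-weighted cosine overlap of two variant sets, in [0, 1].

    0 iff the sets are disjoint; 1 iff they are equal.  Symmetric.
    """
    keys_a, keys_b = profile_a.variant_keys, profile_b.variant_keys
    if not keys_a or not keys_b:
        raise ValueError("clonality score undefined for an empty mutation profile")
    shared = keys_a & keys_b
    wa = _profile_weights(profile_a, pool)
    wb = _profile_weights(profile_b, pool)
    if wa == 0.0 or wb == 0.0:
        # all-weight-zero degenerate profiles (every variant at frequency 1)
        return 1.0 if keys_a == keys_b else 0.0
    ws = sum(pool.weight_of(k) for k in shared)
    return float(ws / np.sqrt(wa * wb))


def pair_seed(master_seed: int, pair: PairKey) -> int:
    """Deterministic per-pair seed from (master_seed, pair identity).

    Independent of pair iteration order; stable across platforms.
    """
    payload = f"{master_seed}|{pair.biopsy_a}|{pair.biopsy_b}".encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def permutation_pvalue(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    pool: VariantPool,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Permutation p-value for the observed clonality score.

    Each replicate redraws variant sets of sizes ``|A|`` and ``|B|`` from
    the pool (frequency-proportional, without replacement) and rescores.
    Ties count against the observed score (>=, conservative).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n_a, n_b = len(profile_a), len(profile_b)
    if max(n_a, n_b) > len(pool):
        raise ValueError(
            f"pool of {len(pool)} variants smaller than a profile ({max(n_a, n_b)})"
        )
    s_obs = clonality_score(profile_a, profile_b, pool)
    rng = np.random.default_rng([seed])
    draws_a = pool.sample_sets(rng, n_a, n_perm)
    draws_b = pool.sample_sets(rng, n_b, n_perm)
    w = pool.weights
    member = np.zeros((n_perm, len(pool)), dtype=bool)
    rows = np.arange(n_perm)[:, None]
    member[rows, draws_a] = True
    shared_w = np.where(member[rows, draws_b], w[draws_b], 0.0).sum(axis=1)
    wa = w[draws_a].sum(axis=1)
    wb = w[draws_b].sum(axis=1)
    denom = np.sqrt(wa * wb)
    null = np.divide(shared_w, denom, out=np.zeros(n_perm), where=denom > 0)
    # float-safe >= : a null score within 1e-12 of the observed counts as a tie
    n_ge = int((null >= s_obs - 1e-12).sum())
    p = (1.0 + n_ge) / (n_perm + 1.0)
    return p, null


def call_pair(
    pair: PairKey,
    score: float,
    p_value: float,
    n_perm: int,
    seed: int,
    n_shared: int = 0,
    alpha_clonal: float = DEFAULT_ALPHA,
) -> ClonalityResult:
    """Binary clonal/non-clonal call: clonal iff p <= alpha (inclusive)."""
    call = "clonal" if p_value <= alpha_clonal else "non_clonal"
    return ClonalityResult(
        pair=pair, score=score, p_value=p_value, n_perm=n_perm,
        call=call, seed=seed, n_shared=n_shared,
    )


def enumerate_tumor_pairs(cohort: Cohort) -> List[PairKey]:
    """All intra-patient, inter-nodule tumor biopsy pairs (canonical order).

    Pairs of biopsies from the same nodule are multi-region samples of one
    tumor and are never scored for clonality.
    """
    pairs = []
    tumors = cohort.tumor_samples
    for i in range(len(tumors)):
        for j in range(i + 1, len(tumors)):
            a, b = tumors[i], tumors[j]
            if a.patient_id != b.patient_id or a.nodule_id == b.nodule_id:
                continue
            pairs.append(PairKey.make(a.biopsy_id, b.biopsy_id))
    return sorted(pairs, key=lambda p: (p.biopsy_a, p.biopsy_b))


def score_all_pairs(
    cohort: Cohort,
    n_perm: int = DEFAULT_N_PERM,
    alpha_clonal: float = DEFAULT_ALPHA,
    master_seed: int = 0,
    f_min: Optional[float] = None,
    pool: Optional[VariantPool] = None,
) -> List[ClonalityResult]:
    """Score every intra-patient inter-nodule biopsy pair of the cohort.

    Per-pair RNG streams are derived from (master_seed, pair identity), so
    results do not depend on iteration order.
    """
    if pool is None:
        pool = VariantPool.from_profiles(cohort.mutations.values(), f_min=f_min)
    results = []
    for pair in enumerate_tumor_pairs(cohort):
        pa = cohort.mutations[pair.biopsy_a]
        pb = cohort.mutations[pair.biopsy_b]
        seed = pair_seed(master_seed, pair)
        score = clonality_score(pa, pb, pool)
        p, _ = permutation_pvalue(pa, pb, pool, n_perm=n_perm, seed=seed)
        n_shared = len(pa.variant_keys & pb.variant_keys)
        results.append(
            call_pair(pair, score, p, n_perm, seed, n_shared, alpha_clonal)
        )
    return results


def results_to_frame(results: Sequence[ClonalityResult], cohort: Optional[Cohort] = None):
    """Tabulate clonality results (one row per biopsy pair)."""
    import pandas as pd

    by_id = {s.biopsy_id: s for s in cohort.samples} if cohort else {}
    rows = []
    for r in results:
        rows.append(
            {
                "biopsy_a": r.pair.biopsy_a,
                "biopsy_b": r.pair.biopsy_b,
                "patient_a": by_id[r.pair.biopsy_a].patient_id if by_id else "",
                "patient_b": by_id[r.pair.biopsy_b].patient_id if by_id else "",
                "n_shared": r.n_shared,
                "score": r.score,
                "p_value": r.p_value,
                "call": r.call,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "biopsy_a", "biopsy_b", "patient_a", "patient_b",
            "n_shared", "score", "p_value", "call", "seed",
        ],
    )
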
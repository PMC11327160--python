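"""Synonymous divergence (Nei-Gojobori 1986) and Ks-peak mixture fitting.

Ks — synonymous substitutions per synonymous site — is the molecular-clock
proxy used to date whole-genome duplications: every polyploidy event leaves
a unimodal peak in the Ks distribution of the paralog pairs it created.
This module provides the counting estimator (NG86 with Jukes-Cantor
correction), per-block median summaries, and Gaussian-mixture fitting with
BIC model selection to locate the peaks.

NG86 conventions used here
--------------------------
* Synonymous sites per codon: at each of the three positions the synonymous
  fraction is (synonymous single-nucleotide changes) / (possible changes),
  where changes creating stop codons are excluded from the possible set;
  the nonsynonymous fraction is its complement, so S + N = 3 per compared
  codon.  Sites are averaged over the two sequences.
* Codons differing at several positions: synonymous/nonsynonymous
  difference counts are averaged over all orderings of single steps,
  excluding orderings that pass through a stop codon (all orderings are
  used if every one of them does).
* Proportions are Jukes-Cantor corrected, d = -3/4 ln(1 - 4p/3); pS >= 3/4
  is reported as saturation (ds undefined), not an error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .genome_model import ValidationError

__all__ = [
    "KsEstimate",
    "KsMixtureModel",
    "ng_ks",
    "annotate_block_ks",
    "fit_ks_peaks",
    "GENETIC_CODE",
    "synonymous_alternatives",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def synonymous_alternatives(codon: str, pos: int) -> list[str]:
    """Bases that, substituted at ``pos``, give a synonymous non-stop codon."""
    aa = GENETIC_CODE[codon]
    out = []
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
            out.append(b)
    return out


@dataclass(frozen=True)
class KsEstimate:
    """NG86 estimate for one sequence pair.

    ``ds``/``dn`` are ``None`` when the Jukes-Cantor correction saturates
    (proportion >= 3/4).
    """

    ds: float | None
    dn: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def saturated(self) -> bool:
        return self.ds is None


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions for one codon (sums to 3)."""
    aa = GENETIC_CODE[codon]
    s_total = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        if n_valid:
            s_total += n_syn / n_valid
    return s_total, 3.0 - s_total


def _codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over single-step orderings (stop-free orderings preferred)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        pos = diff_pos[0]
        syn = GENETIC_CODE[codon_a] == GENETIC_CODE[codon_b]
        return (1.0, 0.0) if syn else (0.0, 1.0)

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:
        # every ordering passes through a stop codon: fall back to counting
        # over all orderings with stop intermediates treated as nonsynonymous
        def walk_all(order):
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if (
                    cur not in STOP_CODONS
                    and nxt not in STOP_CODONS
                    and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
                ):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            return sd, nd

        valid = [walk_all(order) for order in itertools.permutations(diff_pos)]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng_ks(codon_seq_a: str, codon_seq_b: str) -> KsEstimate:
    """Nei-Gojobori (1986) dS/dN for a pair of aligned, in-frame CDS.

    Codons containing gaps ('-') or ambiguous bases ('N') in either
    sequence are skipped pairwise.  Sequences must be equal length, a
    multiple of three, and free of internal stop codons.
    """
    a = codon_seq_a.upper().replace("U", "T")
    b = codon_seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValidationError("sequence lengths differ")
    if len(a) % 3 != 0:
        raise ValidationError("sequence length is not a multiple of 3")
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        for c in (ca, cb):
            if c in STOP_CODONS:
                raise ValidationError(f"internal stop codon {c} at position {i}")
            if c not in GENETIC_CODE:
                raise ValidationError(f"unrecognized codon {c!r} at position {i}")
        n_codons += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _codon_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    if n_codons == 0:
        raise ValidationError("no comparable codons")
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    return KsEstimate(
        ds=_jukes_cantor(ps),
        dn=_jukes_cantor(pn),
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=s_diffs,
        nonsyn_diffs=n_diffs,
        n_codons=n_codons,
    )


def annotate_block_ks(block, pair_ks: Iterable[float | None]):
    """Set a block's ``median_ks`` to the median of its defined pair Ks
    values (even counts: mean of the central two); flag the block when
    every pair is saturated."""
    defined = sorted(k for k in pair_ks if k is not None)
    if not defined:
        block.median_ks = None
        block.saturated = True
        return block
    block.median_ks = float(np.median(defined))
    block.saturated = False
    return block


@dataclass
class KsMixtureModel:
    """A fitted Gaussian mixture over Ks values.

    Components are (weight, mean, sd) sorted by ascending mean; ``bic_table``
    maps each candidate component count to its BIC.
    """

    components: list[tuple[float, float, float]]
    n_points: int
    bic: float
    seed: int
    bic_table: dict[int, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def means(self) -> list[float]:
        return [m for _, m, _ in self.components]


def fit_ks_peaks(
    values: Sequence[float],
    k_max: int,
    n_restarts: int = 10,
    seed: int = 0,
    ks_floor: float = 0.005,
    ks_ceiling: float = 3.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KsMixtureModel:
    """EM-fit Gaussian mixtures with k = 1..k_max components to a Ks sample
    and keep the component count with the lowest BIC.

    Values outside (ks_floor, ks_ceiling] are trimmed before fitting
    (saturation and allele-level noise); at least 50 values must remain.
    Deterministic given ``seed`` (k-means++-style restarts are seeded).
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    x = np.asarray([v for v in values if v is not None], dtype=float)
    x = x[(x > ks_floor) & (x <= ks_ceiling)]
    if x.size < 50:
        raise ValidationError(
            f"need >= 50 Ks values in ({ks_floor}, {ks_ceiling}], got {x.size}"
        )
    X = x.reshape(-1, 1)
    best = None
    bic_table: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            init_params="k-means++",
            random_state=seed % (2**31 - 1),
            tol=tol,
            max_iter=max_iter,
            reg_covar=1e-8,
        )
        gm.fit(X)
        bic = float(gm.bic(X))
        bic_table[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    order = np.argsort(gm.means_.ravel())
    components = [
        (
            float(gm.weights_[i]),
            float(gm.means_[i, 0]),
            max(1e-4, float(np.sqrt(gm.covariances_[i, 0, 0]))),
        )
        for i in order
    ]
    return KsMixtureModel(
        components=components,
        n_points=int(x.size),
        bic=bic,
        seed=seed,
        bic_table=bic_table,
        converged=bool(gm.converged_),
    )
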
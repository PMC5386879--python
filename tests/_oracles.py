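"""Independent reference implementations used to validate the package.

These deliberately avoid the package's internal machinery: the linkage
oracle sums the two-locus pedigree likelihood over the *full* 16-state
space of every individual by exact tensor contraction of independently
constructed factors (no support pruning, no custom elimination order);
the ROH oracle is a literal transcription of the windowed-scan rules
with plain Python loops.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from autozyg.types import Affection, GenotypeCall, Individual, Pedigree

# --------------------------------------------------------------------------
# Linkage: exhaustive two-locus pedigree likelihood

# haplotypes as (disease_allele, marker_allele) tuples
_HAPS = [(d, m) for d in (0, 1) for m in (0, 1)]
# ordered diplotype states as (paternal_hap, maternal_hap)
_STATES = [(hp, hm) for hp in _HAPS for hm in _HAPS]


def _gamete_prob(gam, parent, theta):
    (dg, mg) = gam
    h = parent  # (paternal_hap, maternal_hap)
    p = 0.0
    for i in (0, 1):
        for j in (0, 1):
            if h[i][0] == dg and h[j][1] == mg:
                p += (1.0 - theta) / 2.0 if i == j else theta / 2.0
    return p


def enum_log10_likelihood(
    pedigree: Pedigree,
    calls: dict[str, int],
    marker_freq: float,
    q: float,
    penetrances: tuple[float, float, float],
    theta: float,
) -> float:
    """log10 P(data | theta) by exact exhaustive summation.

    One 16-state axis per individual; factors (founder priors,
    penetrance x observation, transmissions) are contracted with a
    single ``np.einsum`` call, which performs the full sum exactly.
    """
    ids = [ind.id for ind in pedigree]
    axis = {iid: i for i, iid in enumerate(ids)}
    hapfreq = {
        (d, m): (q if d else 1 - q) * (marker_freq if m else 1 - marker_freq)
        for d, m in _HAPS
    }

    def unary(ind: Individual) -> np.ndarray:
        u = np.zeros(16)
        call = calls.get(ind.id, -1)
        for s, (hp, hm) in enumerate(_STATES):
            w = 1.0
            if ind.is_founder:
                w *= hapfreq[hp] * hapfreq[hm]
            ndis = hp[0] + hm[0]
            if ind.affection is Affection.AFFECTED:
                w *= penetrances[ndis]
            elif ind.affection is Affection.UNAFFECTED:
                w *= 1.0 - penetrances[ndis]
            if call >= 0 and hp[1] + hm[1] != call:
                w = 0.0
            u[s] = w
        return u

    trans = np.zeros((16, 16, 16))
    for c, (gp, gm) in enumerate(_STATES):
        for f in range(16):
            for m in range(16):
                trans[c, f, m] = _gamete_prob(gp, _STATES[f], theta) * _gamete_prob(
                    gm, _STATES[m], theta
                )

    letters = "abcdefghij"
    subs = []
    ops = []
    for ind in pedigree:
        subs.append(letters[axis[ind.id]])
        ops.append(unary(ind))
        if not ind.is_founder:
            subs.append(
                letters[axis[ind.id]]
                + letters[axis[ind.sire_id]]
                + letters[axis[ind.dam_id]]
            )
            ops.append(trans)
    total = float(np.einsum(",".join(subs) + "->", *ops, optimize="greedy"))
    return math.log10(total) if total > 0 else float("-inf")


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """A random acyclic pedigree of ``n`` members; non-founders pick two
    distinct earlier individuals as parents (both-or-none)."""
    inds = [Individual("I1"), Individual("I2")]
    for k in range(3, n + 1):
        if rng.random() < 0.6 and len(inds) >= 2:
            a, b = rng.choice(len(inds), size=2, replace=False)
            inds.append(
                Individual(f"I{k}", sire_id=f"I{a + 1}", dam_id=f"I{b + 1}")
            )
        else:
            inds.append(Individual(f"I{k}"))
    out = []
    for ind in inds:
        aff = [Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN][
            int(rng.integers(3))
        ]
        out.append(
            Individual(ind.id, ind.sire_id, ind.dam_id, affection=aff)
        )
    return Pedigree(out)


# --------------------------------------------------------------------------
# ROH: naive windowed scan

def naive_roh(genotypes, positions, params):
    """Literal windowed-scan reference: returns a list of
    (start_idx, end_idx) maximal in-ROH runs passing the thresholds."""
    n = len(genotypes)
    w = min(params.window_snps, n)
    win_ok = []
    for s in range(n - w + 1):
        window = genotypes[s : s + w]
        n_het = sum(1 for g in window if g == GenotypeCall.HET)
        n_mis = sum(1 for g in window if g == GenotypeCall.MISSING)
        win_ok.append(
            n_het <= params.max_het_in_window
            and n_mis <= params.max_missing_in_window
        )
    in_roh = []
    for i in range(n):
        covering = [
            win_ok[s] for s in range(max(0, i - w + 1), min(i, n - w) + 1)
        ]
        frac = sum(covering) / len(covering)
        in_roh.append(frac >= params.min_window_hit_fraction)
    runs = []
    i = 0
    while i < n:
        if in_roh[i]:
            j = i
            while j + 1 < n and in_roh[j + 1]:
                j += 1
            n_snps = j - i + 1
            length = positions[j] - positions[i]
            if n_snps >= params.min_run_snps and length >= params.min_run_length_bp:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs
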
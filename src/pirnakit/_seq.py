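"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA sequence."""
    return "".join(rng.choice(list(DNA), size=length))


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of ``needle`` in ``haystack``."""
    out: list[int] = []
    if not needle:
        return out
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def hamming(a: str, b: str) -> int:
    """Hamming distance; an N in either string never matches."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def discrete_truncnorm_pmf(mean: float, sd: float, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """PMF of a normal discretised to the integers ``lo..hi`` (inclusive).

    Weights are the Gaussian density at each integer, renormalised. The
    location parameter is calibrated (by bisection) so that the mean of the
    *discretised, truncated* law equals ``mean``: the configured mean is the
    observable mean, not the latent one, which matters when ``mean`` sits
    within a couple of standard deviations of a boundary.
    """
    lengths = np.arange(lo, hi + 1)

    def pmf_for(mu: float) -> np.ndarray:
        w = np.exp(-0.5 * ((lengths - mu) / sd) ** 2)
        return w / w.sum()

    a, b = mean - 3 * sd, mean + 3 * sd
    for _ in range(60):
        mid = (a + b) / 2
        if float(lengths @ pmf_for(mid)) < mean:
            a = mid
        else:
            b = mid
    return lengths, pmf_for((a + b) / 2)
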
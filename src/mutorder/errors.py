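"""Observation model for single-cell genotype calls.

True genotypes are binary (0 wildtype, 1 heterozygous; a true homozygous
mutation at a base pair is considered too unlikely to model), while observed
calls live in {0, 1, 2}. Two MDA sequencing-error modes connect them:

* false discovery (FD): a true wildtype called heterozygous;
* allelic dropout (AD): a true heterozygote called homozygous, split
  evenly between 0 and 2.

A residual rate ``c`` of calling a true wildtype homozygous-mutant is kept
as a parameter but defaults to 0 (negligible next to FD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Allelic-dropout and false-discovery rates of the MDA single-cell
#: exome study the packaged fixture comes from.
DEFAULT_FD: float = 6.04e-5
DEFAULT_AD: float = 0.4309


@dataclass(frozen=True)
class ErrorRates:
    """Global sequencing-error rates.

    fd : P(observe 1 | true 0), false discovery
    ad : P(observe 0 or 2 | true 1), allelic dropout
    c  : P(observe 2 | true 0), residual homozygous miscall
    """

    fd: float = DEFAULT_FD
    ad: float = DEFAULT_AD
    c: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fd", "ad", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fd + self.c > 1.0:
            raise ValueError(f"fd + c = {self.fd + self.c} exceeds 1")


def observation_probs(e: ErrorRates) -> np.ndarray:
    """2x3 table ``P[true][observed]`` of call probabilities.

    Row 0 (true wildtype): (1-FD-c, FD, c).
    Row 1 (true heterozygote): (AD/2, 1-AD, AD/2).
    Each row sums to 1.
    """
    return np.array([
        [1.0 - e.fd - e.c, e.fd, e.c],
        [e.ad / 2.0, 1.0 - e.ad, e.ad / 2.0],
    ])


def pair_observation_prob(e: ErrorRates, true_pair: tuple[int, int],
                          obs_pair: tuple[int, int]) -> float:
    """P(observed pair | true pair), errors independent across the two sites."""
    ip, jp = true_pair
    i, j = obs_pair
    if ip not in (0, 1) or jp not in (0, 1):
        raise ValueError(f"true genotypes must be 0/1, got {true_pair}")
    if i not in (0, 1, 2) or j not in (0, 1, 2):
        raise ValueError(f"observed genotypes must be 0/1/2, got {obs_pair}")
    P = observation_probs(e)
    return float(P[ip, i] * P[jp, j])
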
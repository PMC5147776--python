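"""Shared helpers: seeded substreams, error types, dosage standardization."""

from __future__ import annotations

import zlib

import numpy as np

MISSING = -1  # sentinel for missing dosage in int8 matrices


class SexgwasError(RuntimeError):
    pass


class FormatError(SexgwasError):
    """Malformed input file (bad magic bytes, inconsistent row counts, ...)."""


class AscertainmentError(SexgwasError):
    """Rejection-sampling budget exhausted before the requested cohort was filled."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a root seed.

    Every stochastic operation draws from its own substream so that modules
    are independently reproducible: changing the number of draws in one
    operation does not perturb any other.
    """
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def standardize_dosages(
    dosages: np.ndarray,
    freqs: np.ndarray,
    ploidy: np.ndarray | int = 2,
) -> np.ndarray:
    """Center/scale allele counts to unit variance under Hardy-Weinberg.

    ``ploidy`` is 2 for autosomal (and female X) dosages and 1 for hemizygous
    male X dosages; it may be an array broadcastable against ``dosages``
    (individuals x SNPs). Missing entries (negative) are replaced by the
    population mean, i.e. contribute 0 after centering.
    """
    d = np.asarray(dosages, dtype=float)
    mean = ploidy * freqs
    var = ploidy * freqs * (1.0 - freqs)
    sd = np.sqrt(np.maximum(var, 1e-12))
    d = np.where(d < 0, mean, d)
    return (d - mean) / sd


def minor_allele_flip(freqs: np.ndarray) -> np.ndarray:
    """Boolean mask of SNPs whose counted allele is the major one (freq > 0.5)."""
    return np.asarray(freqs) > 0.5
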
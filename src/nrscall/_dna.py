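"""Low-level DNA helpers shared across the package.

Sequences are plain Python strings over ``ACGTN`` at the API surface;
hot loops encode them into ``uint8`` numpy arrays (A=0, C=1, G=2, T=3,
N=4) so that k-mer extraction and mismatch counting vectorize.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserving)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DEC[np.minimum(arr, 4)].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. ACGT string of the requested length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer of an encoded sequence (k <= 31).

    Returns ``(codes, valid)`` where ``codes[i]`` packs ``enc[i:i+k]``
    into a uint64 and ``valid[i]`` is False when the window contains a
    non-ACGT base.
    """
    if k > 31:
        raise ValueError("packed k-mers support k <= 31")
    n = len(enc) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    bad = (enc >= 4).astype(np.int32)
    for j in range(k):
        codes = (codes << np.uint64(2)) | np.minimum(enc[j : j + n], 3).astype(np.uint64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def _mix64(x: np.ndarray) -> np.ndarray:
    """Cheap invertible 64-bit mixer (splitmix64 finalizer) for minimizer order."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x
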
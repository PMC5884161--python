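"""Fixed-length binary encodings of the three predictors.

Each predictor feeds its own network: PSA as a 9-bit unsigned binary number
(MSB first, rounded to the nearest integer, clipped to [0, 511] which covers
the observed range up to 440 ng/mL), Gleason as a 9-way one-hot flag vector,
clinical T stage as an 8-way one-hot flag vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CLINICAL_T_CATEGORIES, GLEASON_CATEGORIES, PatientRecord, _match_category

__all__ = [
    "EncodedFeatures",
    "encode_psa",
    "decode_psa_bits",
    "encode_gleason",
    "encode_clinical_t",
    "encode_record",
    "encode_cohort",
    "FEATURE_DIMS",
]

PSA_BITS = 9
PSA_MAX_INT = 2**PSA_BITS - 1  # 511

#: Input width per feature-specific classifier.
FEATURE_DIMS = {"initial_psa": 9, "gleason": 9, "clinical_t": 8}


@dataclass(frozen=True)
class EncodedFeatures:
    """The three bit vectors consumed by the three feature classifiers."""

    psa_bits: np.ndarray
    gleason_flags: np.ndarray
    clinical_t_flags: np.ndarray

    def __post_init__(self) -> None:
        for name, vec, n in (
            ("psa_bits", self.psa_bits, 9),
            ("gleason_flags", self.gleason_flags, 9),
            ("clinical_t_flags", self.clinical_t_flags, 8),
        ):
            vec = np.asarray(vec, dtype=np.int8)
            if vec.shape != (n,) or not np.isin(vec, (0, 1)).all():
                raise ValueError(f"{name} must be a length-{n} 0/1 vector")
            object.__setattr__(self, name, vec)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "initial_psa": self.psa_bits,
            "gleason": self.gleason_flags,
            "clinical_t": self.clinical_t_flags,
        }


def encode_psa(psa: float) -> np.ndarray:
    """Encode a PSA level (ng/mL) as 9 binary digits, MSB first.

    The value is rounded to the nearest integer (ties to even) and clipped
    to [0, 511].  The decoded integer is therefore ``min(round(psa), 511)``.
    """
    if not np.isfinite(psa) or psa <= 0:
        raise ValueError(f"psa must be positive and finite, got {psa!r}")
    value = min(int(np.rint(psa)), PSA_MAX_INT)
    bits = [(value >> (PSA_BITS - 1 - i)) & 1 for i in range(PSA_BITS)]
    return np.array(bits, dtype=np.int8)


def decode_psa_bits(bits: np.ndarray) -> int:
    """Inverse of :func:`encode_psa` on the integer scale."""
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (PSA_BITS,):
        raise ValueError(f"expected {PSA_BITS} bits, got shape {bits.shape}")
    return int(sum(b << (PSA_BITS - 1 - i) for i, b in enumerate(bits)))


def _one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n, dtype=np.int8)
    v[index] = 1
    return v


def encode_gleason(gleason: str | int) -> np.ndarray:
    """One-hot over [3, 4, 5, 6, 7(3+4), 7(4+3), 8, 9, 10]."""
    g = _match_category(gleason, GLEASON_CATEGORIES, "gleason")
    return _one_hot(GLEASON_CATEGORIES.index(g), len(GLEASON_CATEGORIES))


def encode_clinical_t(clinical_t: str) -> np.ndarray:
    """One-hot over [T1a, T1b, T1c, T2a, T2b, T2c, T3a, T3b]."""
    t = _match_category(clinical_t, CLINICAL_T_CATEGORIES, "clinical T")
    return _one_hot(CLINICAL_T_CATEGORIES.index(t), len(CLINICAL_T_CATEGORIES))


def encode_record(record: PatientRecord) -> EncodedFeatures:
    """Encode one patient's three predictors."""
    return EncodedFeatures(
        psa_bits=encode_psa(record.psa),
        gleason_flags=encode_gleason(record.gleason),
        clinical_t_flags=encode_clinical_t(record.clinical_t),
    )


def encode_cohort(records) -> dict[str, np.ndarray]:
    """Stack encodings for a record sequence into per-feature float matrices."""
    encoded = [encode_record(r) for r in records]
    return {
        "initial_psa": np.array([e.psa_bits for e in encoded], dtype=float),
        "gleason": np.array([e.gleason_flags for e in encoded], dtype=float),
        "clinical_t": np.array([e.clinical_t_flags for e in encoded], dtype=float),
    }
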
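"""Analytic model of sequencing errors in duplex tags.

A read pair whose 24-bp barcode (the two concatenated 12-bp tags) contains
even a single error is almost certainly assigned a brand-new, unique barcode
and therefore founds an artifactual single-read family.  With a per-base
error rate E accumulated over the whole protocol, the fraction of barcodes
carrying at least one error is

    r = 1 - (1 - E)**l

with l the barcode length.  The same expression composes error rates across
protocol stages (PCR cycles plus the sequencing reaction, with E the
per-base per-stage rate and l the stage count), and inverts to estimate the
cumulative per-base error rate from an observed singleton-family fraction.

The model keeps two deliberate simplifications: every erroneous barcode is
unique (no collisions), and errors occur only within tags.  Both overcount
slightly, which is acceptable for the order-of-magnitude accounting the
model is used for.
"""

from __future__ import annotations

import math


def _check_prob(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


def erroneous_fraction(E: float, l: int) -> float:
    """Fraction of l-base barcodes expected to contain at least one error."""
    _check_prob(E, "E")
    if l < 1:
        raise ValueError("l must be a positive integer")
    return 1.0 - (1.0 - E) ** l


def cumulative_error(per_stage_E: float, n_stages: int) -> float:
    """Per-base error rate accumulated over independent protocol stages.

    The stage count for a duplex run is the number of PCR cycles plus one
    for the sequencing reaction (e.g. 30 + 1 = 31).
    """
    return erroneous_fraction(per_stage_E, n_stages)


def invert_for_E(r: float, l: int) -> float:
    """Per-base error rate that produces erroneous-barcode fraction ``r``.

    Solves r = 1 - (1-E)**l for E; the roundtrip with
    :func:`erroneous_fraction` is exact to machine precision.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must be in [0, 1), got {r}")
    if l < 1:
        raise ValueError("l must be a positive integer")
    return 1.0 - (1.0 - r) ** (1.0 / l)


def singleton_error_estimate(n_singleton_families: int, n_total_read_pairs: int) -> float:
    """Erroneous-barcode fraction estimated from singleton families.

    Under the model's assumption that every single-read family is the
    byproduct of a barcode error, the erroneous fraction is simply
    singletons / total read pairs.
    """
    if n_singleton_families < 0 or n_total_read_pairs < 0:
        raise ValueError("counts must be non-negative")
    if n_total_read_pairs == 0:
        raise ValueError("total read pairs must be positive")
    return n_singleton_families / n_total_read_pairs


def expected_observed_families(n_fragments: int, n_read_pairs: int, r: float) -> int:
    """Expected family count when a fraction r of barcodes carry errors.

    Every erroneous barcode is assumed unique and to spawn one singleton
    family, so the expectation is ``n_fragments + round(n_read_pairs * r)``
    (half-up rounding, presentation-level).
    """
    if n_fragments < 0 or n_read_pairs < 0:
        raise ValueError("counts must be non-negative")
    _check_prob(r, "r")
    return n_fragments + int(math.floor(n_read_pairs * r + 0.5))


def barcode_stats_from_census(
    census: dict[str, int], barcode_len: int = 24, n_stages: int | None = None
) -> dict[str, float]:
    """Error-rate estimates from a family census.

    Counts every canonical barcode seen with exactly one read pair as a
    singleton family, estimates the erroneous-barcode fraction r_hat and the
    cumulative per-base error rate E_hat; with ``n_stages`` given, also the
    per-stage rate.
    """
    n_single = census["unique_tags_with_1_pair"]
    n_pairs = census["read_pairs"]
    r_hat = singleton_error_estimate(n_single, n_pairs)
    out = {
        "n_singleton_families": float(n_single),
        "n_read_pairs": float(n_pairs),
        "r_hat": r_hat,
        "E_hat": invert_for_E(r_hat, barcode_len),
    }
    if n_stages is not None:
        out["per_stage_E_hat"] = invert_for_E(out["E_hat"], n_stages)
    return out
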
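"""Small shared helpers: chromosome naming, rounding, interval arithmetic."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def normalise_chrom(chrom: str) -> str:
    """Normalise a chromosome label to the ``chr``-prefixed convention.

    Accepts both ``"3"`` and ``"chr3"`` (mixed conventions are common across
    VCF and BED sources) and returns ``"chr3"``.
    """
    chrom = str(chrom).strip()
    if not chrom:
        raise ValueError("empty chromosome label")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as report tables are printed.

    Python's builtin ``round`` is banker's rounding; printed summary tables
    use half-up (2.5 -> 3), so display formatting goes through this.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
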
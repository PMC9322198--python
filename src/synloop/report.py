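"""Summary arithmetic for stage reports: partitions and percentages."""

from __future__ import annotations

from typing import Mapping, Sequence


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded for reporting."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * count / total, decimals)


def partition_ok(parts: Sequence[int], total: int) -> bool:
    """True when the class counts exactly partition the total."""
    return sum(parts) == total


def partition_report(class_counts: Mapping[str, int], total: int,
                     decimals: int = 1) -> dict:
    """Per-class counts and percentages plus the partition identity check."""
    out = {
        "total": total,
        "classes": {},
        "partition_ok": partition_ok(list(class_counts.values()), total),
    }
    for name, count in class_counts.items():
        out["classes"][name] = {
            "count": count,
            "pct": percentage(count, total, decimals),
        }
    return out
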
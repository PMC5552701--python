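"""Small shared helpers: rounding to printed precision, chromosome name parsing."""

from __future__ import annotations

import decimal
import re

_CHROM_RE = re.compile(r"^(\d+)([A-Za-z])[SL]?$")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in round() is banker's rounding; densities such as
    markers/cM and coverage percentages are conventionally reported with
    half-up rounding, so that is what all summary writers use.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def parse_chromosome(name: str, nomenclature: dict | None = None) -> tuple[int, str]:
    """Parse a chromosome name into (homoeologous group, genome letter).

    The default parser handles wheat-style names: a group digit followed by a
    genome letter, optionally with an arm suffix (``1A``, ``3B``, ``1AS``).
    Other nomenclatures can be supplied as an explicit mapping
    ``{name: (group, genome)}``.
    """
    if nomenclature is not None:
        if name in nomenclature:
            group, genome = nomenclature[name]
            return int(group), str(genome)
        raise ValueError(f"chromosome {name!r} missing from nomenclature table")
    m = _CHROM_RE.match(str(name).strip())
    if m is None:
        raise ValueError(f"cannot parse chromosome name {name!r} as <group><genome>")
    return int(m.group(1)), m.group(2).upper()
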
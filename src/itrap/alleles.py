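"""HLA allele name canonicalization.

Input tables mix dialects ("A0201", "HLA-A*02:01", "B*08:01", "HLA*A-03:01").
All comparisons in the package happen at two-field resolution in the canonical
form ``LOCUS*NN:NN`` (e.g. ``A*02:01``).
"""

from __future__ import annotations

import re

from .errors import DataFormatError

# locus letters, optional separators, then the numeric fields
_ALLELE_RE = re.compile(
    r"^(?:HLA[-*]?)?\s*(DRB[1-9]|DQA1|DQB1|DPA1|DPB1|[A-Z]+)[\s*-]*([0-9:.]+)$"
)


def canonicalize_allele(raw: str) -> str:
    """Normalize an HLA allele string to two-field ``LOCUS*NN:NN`` form.

    >>> canonicalize_allele("A0201")
    'A*02:01'
    >>> canonicalize_allele("HLA-A*02:01:01")
    'A*02:01'
    """
    if raw is None:
        raise DataFormatError("HLA allele is missing")
    s = str(raw).strip().upper()
    m = _ALLELE_RE.match(s)
    if not m:
        raise DataFormatError(f"cannot parse HLA allele {raw!r}")
    locus, fields = m.groups()
    digits = re.split(r"[:.]", fields)
    if len(digits) == 1:
        d = digits[0]
        if len(d) < 4 or len(d) % 2:
            # pad 3-digit group fields like A*101 -> heuristically reject
            if len(d) == 3:
                digits = [d[0].zfill(2), d[1:]]
            else:
                raise DataFormatError(f"cannot parse HLA allele {raw!r}")
        else:
            # digit runs of 4+ read as two-digit fields: "0201[01...]" -> 02:01
            digits = [d[0:2], d[2:4]]
    group, protein = digits[0], digits[1]
    return f"{locus}*{int(group):02d}:{int(protein):02d}"


def allele_set(alleles) -> frozenset[str]:
    """Canonicalize an iterable of allele strings into a frozenset."""
    return frozenset(canonicalize_allele(a) for a in alleles)
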
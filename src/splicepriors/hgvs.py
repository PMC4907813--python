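"""Restricted HGVS c. parsing against a gene model.

Supports the variant descriptions the splice pipeline consumes: coding SNVs
(``c.7709A>C``), intronic-offset SNVs near splice junctions (``c.632-16A>C``,
``c.100+5G>T``), and simple del/dup/ins (``c.4479_4484+2dup``).  Anything
else raises :class:`UnsupportedHgvsError` — no silent guesses.  Offsets of
any size parse; scope (the -20..+6 proximal window) is decided downstream by
the gene model's region classification.
"""

from __future__ import annotations

import re

from .gene_model import (
    OrientedGene,
    OrientedVariant,
    ReferenceMismatchError,
    VariantKind,
    VariantRecord,
)

__all__ = ["UnsupportedHgvsError", "parse_hgvs_c", "format_hgvs_c"]


class UnsupportedHgvsError(ValueError):
    """Expression kind outside the restricted HGVS subset."""


_POS = r"(\d+)(?:([+-])(\d+))?"
_SNV_RE = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_DEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?del$")
_DUP_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?dup$")
_INS_RE = re.compile(rf"^c\.{_POS}_{_POS}ins([ACGT]+)$")


def _resolve(gene: OrientedGene, c: str, sign: str | None, off: str | None) -> int:
    opos = gene.cdna_to_oriented(int(c))
    if sign == "+":
        return opos + int(off)
    if sign == "-":
        return opos - int(off)
    return opos


def parse_hgvs_c(expression: str, gene: OrientedGene) -> VariantRecord:
    """Parse a c. expression into a genomic :class:`VariantRecord`."""
    expr = expression.strip()
    m = _SNV_RE.match(expr)
    if m:
        c, sign, off, ref, alt = m.groups()
        opos = _resolve(gene, c, sign, off)
        if not 0 <= opos < len(gene.seq):
            raise UnsupportedHgvsError(f"{expr}: position outside the modeled span")
        if gene.seq[opos] != ref:
            raise ReferenceMismatchError(
                f"{expr}: reference has {gene.seq[opos]!r} at that position, "
                f"not {ref!r}"
            )
        return gene.deorient_variant(OrientedVariant(opos, ref, alt))
    m = _DUP_RE.match(expr)
    if m:
        c1, s1, o1, c2, s2, o2 = m.groups()
        lo = _resolve(gene, c1, s1, o1)
        hi = lo if c2 is None else _resolve(gene, c2, s2, o2)
        if hi < lo:
            raise UnsupportedHgvsError(f"{expr}: inverted interval")
        dup = gene.seq[lo : hi + 1]
        anchor = gene.seq[hi]
        return gene.deorient_variant(OrientedVariant(hi, anchor, anchor + dup))
    m = _DEL_RE.match(expr)
    if m:
        c1, s1, o1, c2, s2, o2 = m.groups()
        lo = _resolve(gene, c1, s1, o1)
        hi = lo if c2 is None else _resolve(gene, c2, s2, o2)
        if hi < lo:
            raise UnsupportedHgvsError(f"{expr}: inverted interval")
        if lo == 0:
            raise UnsupportedHgvsError(f"{expr}: deletion lacks an anchor base")
        anchor = gene.seq[lo - 1]
        return gene.deorient_variant(
            OrientedVariant(lo - 1, anchor + gene.seq[lo : hi + 1], anchor)
        )
    m = _INS_RE.match(expr)
    if m:
        c1, s1, o1, c2, s2, o2, inserted = m.groups()
        lo = _resolve(gene, c1, s1, o1)
        hi = _resolve(gene, c2, s2, o2)
        if hi != lo + 1:
            raise UnsupportedHgvsError(
                f"{expr}: insertion flanks must be adjacent positions"
            )
        anchor = gene.seq[lo]
        return gene.deorient_variant(OrientedVariant(lo, anchor, anchor + inserted))
    raise UnsupportedHgvsError(f"unsupported HGVS c. expression: {expression!r}")


def _format_pos(gene: OrientedGene, opos: int) -> str:
    c, off = gene.oriented_to_cdna(opos)
    if off == 0:
        return str(c)
    return f"{c}{off:+d}"


def format_hgvs_c(variant: VariantRecord, gene: OrientedGene) -> str:
    """Normalized c. string for a variant (SNV and simple del/dup/ins)."""
    ov = gene.orient_variant(variant)
    kind = ov.kind
    if kind is VariantKind.SNV:
        return f"c.{_format_pos(gene, ov.start)}{ov.ref}>{ov.alt}"
    if kind is VariantKind.DELETION:
        lo = ov.start + len(ov.alt)
        hi = ov.end - 1
        if lo == hi:
            return f"c.{_format_pos(gene, lo)}del"
        return f"c.{_format_pos(gene, lo)}_{_format_pos(gene, hi)}del"
    if kind is VariantKind.INSERTION:
        inserted = ov.alt[len(ov.ref) :]
        hi = ov.start + len(ov.ref) - 1
        lo = hi - len(inserted) + 1
        if lo >= 0 and gene.seq[lo : hi + 1] == inserted:
            if lo == hi:
                return f"c.{_format_pos(gene, lo)}dup"
            return f"c.{_format_pos(gene, lo)}_{_format_pos(gene, hi)}dup"
        return (
            f"c.{_format_pos(gene, hi)}_{_format_pos(gene, hi + 1)}ins{inserted}"
        )
    raise UnsupportedHgvsError(f"cannot format variant of kind {kind.value}")
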
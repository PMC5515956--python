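"""Classify a variant's effect from HGVS-style cDNA / protein change strings.

This is deliberately a string classifier, not an annotator: the upstream
annotation tool already decided the change strings, and the pipeline only
needs the coarse effect class (missense / nonsense / frameshift / splice-site
/ in-frame deletion / synonymous) for reporting and the synonymous-drop rule.

Conventions handled:

* intronic offsets near an exon edge, e.g. ``c.294-2A > T`` or
  ``c.1207 + 3G > C`` → splice site.  An ASCII ``+``/``-`` between two
  numbers marks an offset; typeset en-dashes (``c.739–750 del...``) denote
  position ranges and are never read as offsets.  Offsets are capped at
  ``MAX_SPLICE_OFFSET`` so a hyphenated range is not mistaken for a deep
  intronic offset.
* ``fs`` anywhere in the protein change → frameshift.
* a substitution ending in ``X`` or ``*`` (e.g. ``p.W91X``) → nonsense.
* ``del`` without a frameshift (whole codons) → in-frame deletion.
* single-residue substitution ``p.V633F`` → missense (same residue →
  synonymous).
"""

from __future__ import annotations

import logging
import re
from typing import Optional

from .model import Effect

log = logging.getLogger(__name__)

#: Largest intronic offset still treated as a splice-region change.
MAX_SPLICE_OFFSET = 50

_OFFSET_RE = re.compile(r"\d+\s*[+-]\s*(\d+)")
_AA_SUB_RE = re.compile(r"^p\.\(?([A-Z])(?:[a-z]{2})?(\d+)([A-Z])(?:[a-z]{2})?\)?$")
_NONSENSE_RE = re.compile(r"^p\.\(?[A-Z](?:[a-z]{2})?\d+(?:X|\*|Ter)\)?$")


def _normalize(s: Optional[str]) -> Optional[str]:
    if s is None:
        return None
    s = s.strip()
    if not s or s.upper() in ("NA", "N/A", "NONE", "_", "."):
        return None
    return s.replace(" ", "")


def _has_splice_offset(cdna: str) -> bool:
    for m in _OFFSET_RE.finditer(cdna):
        if 1 <= int(m.group(1)) <= MAX_SPLICE_OFFSET:
            return True
    return False


def parse_hgvs_effect(cdna_change: Optional[str], protein_change: Optional[str]) -> Effect:
    """Map HGVS-style change strings onto one coarse effect class.

    At least one of the two strings must be present; unparseable input yields
    ``Effect.OTHER`` with a logged warning.
    """
    cdna = _normalize(cdna_change)
    prot = _normalize(protein_change)
    if cdna is None and prot is None:
        raise ValueError("need a cDNA or a protein change string")

    # Intron-boundary offsets win even when an (often nominal) protein change
    # is printed alongside, e.g. a deletion spanning an exon/intron junction.
    if cdna is not None and _has_splice_offset(cdna):
        return Effect.SPLICE_SITE

    if prot is not None:
        if "fs" in prot:
            return Effect.FRAMESHIFT
        if _NONSENSE_RE.match(prot):
            return Effect.NONSENSE
        if "del" in prot:
            return Effect.INFRAME_DELETION
        m = _AA_SUB_RE.match(prot)
        if m:
            return Effect.SYNONYMOUS if m.group(1) == m.group(3) else Effect.MISSENSE
        if prot in ("p.=",):
            return Effect.SYNONYMOUS

    if cdna is not None:
        m = re.search(r"(?:del|dup)([ACGT]+)$", cdna)
        if m:
            return Effect.INFRAME_DELETION if len(m.group(1)) % 3 == 0 else Effect.FRAMESHIFT
        if re.search(r"(?:del|dup|ins)", cdna):
            return Effect.OTHER
        if re.search(r"[ACGT]>[ACGT]", cdna) and prot is None:
            # Substitution with no protein consequence recorded.
            return Effect.OTHER

    log.warning("unparseable HGVS change: cdna=%r protein=%r", cdna_change, protein_change)
    return Effect.OTHER
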
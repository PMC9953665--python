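"""ORF finding, translation, decay classification and stop-loss extension."""

from __future__ import annotations

import re
from typing import Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .models import (
    DECAY_NMD,
    DECAY_NONSTOP,
    DECAY_NORMAL,
    ProteinRecord,
    TranscriptModel,
)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)

#: nt between a stop codon's 3' end and the last exon junction beyond which
#: a transcript is predicted to undergo nonsense-mediated decay.
DEFAULT_NMD_THRESHOLD = 50

_EXT_RE = re.compile(r"^p\.Ter(\d+)([A-Z][a-z]{2})extTer(\d+|\?)$")


class StopLossError(ValueError):
    """An edit presented as a stop-loss does not abolish the stop codon."""


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for stop, 'X' for ambiguous."""
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def _translate_span(sequence: str, start: int, end: Optional[int] = None) -> Tuple[str, bool, int]:
    """Translate codons from ``start`` until stop, ``end`` or sequence end.

    Returns (protein, stop_reached, span_end) where span_end includes the
    stop codon when one was reached.
    """
    limit = len(sequence) if end is None else end
    aa = []
    pos = start
    while pos + 3 <= limit:
        codon = sequence[pos : pos + 3]
        res = translate_codon(codon)
        if res == "*":
            return "".join(aa), True, pos + 3
        aa.append(res)
        pos += 3
    return "".join(aa), False, pos


def find_orf_translate(
    tx_sequence: str,
    cds_span: Optional[Tuple[int, int]] = None,
    cds_partial: bool = False,
    source_transcript_id: Optional[str] = None,
) -> ProteinRecord:
    """Translate an annotated CDS, or the longest ATG-initiated ORF.

    With ``cds_span`` the translation starts at its 5' end and stops at the
    first in-frame stop codon (or the span/sequence end).  Without it every
    ATG is scanned and the longest resulting protein wins; ties go to the
    most 5' start.
    """
    if not tx_sequence:
        raise ValueError("empty transcript sequence")
    if cds_span is not None:
        cs, ce = cds_span
        if (ce - cs) % 3 != 0 and not cds_partial:
            raise ValueError("cds_span length not divisible by 3 and not flagged partial")
        protein, stop, span_end = _translate_span(tx_sequence, cs, None)
        return ProteinRecord(
            sequence=protein,
            source_transcript_id=source_transcript_id,
            orf_span=(cs, span_end),
            stop_reached=stop,
        )

    best: Optional[Tuple[str, bool, int, int]] = None
    for m in re.finditer("ATG", tx_sequence):
        start = m.start()
        protein, stop, span_end = _translate_span(tx_sequence, start)
        if not protein:
            continue
        if best is None or len(protein) > len(best[0]):
            best = (protein, stop, start, span_end)
    if best is None:
        raise ValueError("no ATG-initiated ORF found")
    protein, stop, start, span_end = best
    return ProteinRecord(
        sequence=protein,
        source_transcript_id=source_transcript_id,
        orf_span=(start, span_end),
        stop_reached=stop,
    )


def classify_decay_from_junctions(
    exon_junctions: Sequence[int],
    orf_span: Tuple[int, int],
    stop_reached: bool,
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> str:
    """Apply the NMD/nonstop decision rule in transcript coordinates.

    ``nmd_predicted`` when the stop codon ends more than ``nmd_threshold``
    nt upstream of the final exon-exon junction; ``nonstop_predicted`` when
    no in-frame stop was reached before the transcript end.
    """
    if not stop_reached:
        return DECAY_NONSTOP
    if not exon_junctions:
        return DECAY_NORMAL
    last_junction = max(exon_junctions)
    if last_junction - orf_span[1] > nmd_threshold:
        return DECAY_NMD
    return DECAY_NORMAL


def classify_decay(
    tx: TranscriptModel,
    protein: ProteinRecord,
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> str:
    return classify_decay_from_junctions(
        tx.exon_junctions, protein.orf_span, protein.stop_reached, nmd_threshold
    )


def parse_extension_name(name: str) -> Tuple[int, str, Optional[int], Optional[int]]:
    """Parse p.Ter{N}{Aa}extTer{M} -> (N, Aa, M, added residues).

    M - 1 residues are appended before the new stop; an open extension
    (extTer?) has both M and the added count unknown (None).
    """
    m = _EXT_RE.match(name)
    if m is None:
        raise ValueError(f"not an HGVS stop-loss extension name: {name!r}")
    n = int(m.group(1))
    aa = m.group(2)
    if m.group(3) == "?":
        return n, aa, None, None
    ext = int(m.group(3))
    return n, aa, ext, ext - 1


def apply_stop_loss_retranslate(
    tx_sequence: str,
    orf_span: Tuple[int, int],
    edit: Tuple[int, str, str],
    source_transcript_id: Optional[str] = None,
) -> Tuple[ProteinRecord, str]:
    """Re-translate past an abolished stop codon into the 3'UTR.

    The edit must overlap the stop codon (the final 3 nt of ``orf_span``)
    and must change it into a sense codon.  Returns the extended protein
    and its HGVS-style extension name p.Ter{N}{Aa}extTer{M}; when no new
    stop is reached the name is open (extTer?) and decay becomes
    nonstop_predicted.
    """
    from .sequence import inject_haplotype  # local import to avoid cycle

    cs, ce = orf_span
    stop_start = ce - 3
    pos, ref, alt = edit
    if pos + len(ref) <= stop_start or pos >= ce:
        raise StopLossError("edit does not overlap the stop codon")
    if tx_sequence[stop_start:ce] not in _STOP_CODONS:
        raise StopLossError("orf_span does not end in a stop codon")

    edited = inject_haplotype(tx_sequence, [edit])
    protein, stop, span_end = _translate_span(edited, cs)
    old_naa = (stop_start - cs) // 3
    if len(protein) <= old_naa and stop:
        raise StopLossError("edit does not abolish the stop codon")

    ter_pos = old_naa + 1
    new_res_at_stop = protein[old_naa]
    ext_residues = len(protein) - old_naa
    if stop:
        name = f"p.Ter{ter_pos}{seq3(new_res_at_stop)}extTer{ext_residues + 1}"
        decay = None
    else:
        name = f"p.Ter{ter_pos}{seq3(new_res_at_stop)}extTer?"
        decay = DECAY_NONSTOP
    record = ProteinRecord(
        sequence=protein,
        source_transcript_id=source_transcript_id,
        orf_span=(cs, span_end),
        stop_reached=stop,
        decay_class=decay,
    )
    return record, name
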
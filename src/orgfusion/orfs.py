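"""Six-frame ORF extraction with circular-contig support.

The caller reports maximal ATG-initiated ORFs: for each (stop codon, frame,
strand) the single ORF starting at the most upstream ATG after the previous
in-frame stop. ``nt_length`` counts the start codon through the last sense
codon and excludes the stop, so the 75-nt minimum corresponds to 25 amino
acids. Alternative start codons (GTG/TTG) are not considered.

Circular contigs are scanned on the doubled sequence; an ORF may span the
origin but never exceeds the contig length. ORFs running off a *linear*
contig end without a stop codon are returned (flagged ``truncated``) only on
request.

Also provides standard-code translation and a Kyte-Doolittle sliding-window
hydropathy scan used as an explicitly simplified stand-in for HMM-based
transmembrane prediction (optional transcript-filter path only).
"""

from __future__ import annotations

from Bio.Seq import Seq

from .records import OrfRecord, SequenceRecord, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

# Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def translate(nt_sequence: str) -> str:
    """Translate a coding nucleotide sequence with the standard code.

    The sequence length must be a multiple of 3 and contain no ambiguity
    codes. A stop codon is rendered as ``*`` only when it is the final codon;
    an internal stop raises ``ValueError``.
    """
    nt = nt_sequence.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    bad = set(nt) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous/invalid bases {sorted(bad)}")
    aa = str(Seq(nt).translate(table=1))
    if "*" in aa[:-1]:
        raise ValueError("internal stop codon before sequence end")
    return aa


def _scan_frames(seq: str, limit: int, cap: int, min_nt: int):
    """Yield candidate ORFs (atg0, stop0, nt_len, terminated) from a linear scan.

    ``seq`` is scanned in all three frames; only ORFs whose ATG lies at a
    0-based position < ``limit`` are yielded; ORFs longer than ``cap`` coding
    bases are discarded (guards circular scans against stop-free frames).
    Unterminated ORFs (no stop before the end of ``seq``) are yielded with
    ``terminated=False`` and stop0 = None.
    """
    n = len(seq)
    for frame in range(3):
        atg = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if atg is not None:
                    nt_len = pos - atg
                    if nt_len >= min_nt and nt_len <= cap and atg < limit:
                        yield atg, pos, nt_len, True
                    atg = None
            elif codon == START_CODON and atg is None:
                atg = pos
        if atg is not None:
            nt_len = (n - atg) - (n - atg) % 3
            if nt_len >= min_nt and nt_len <= cap and atg < limit:
                yield atg, None, nt_len, False


def find_orfs(
    seq: SequenceRecord,
    min_nt: int = 75,
    include_truncated: bool = False,
) -> list[OrfRecord]:
    """All maximal ATG-initiated ORFs with nt_length >= min_nt, both strands."""
    if min_nt < 3 or min_nt % 3 != 0:
        raise ValueError("min_nt must be a positive multiple of 3")
    L = len(seq)
    results: dict[tuple, tuple] = {}
    order = []
    for strand in ("+", "-"):
        s = seq.sequence if strand == "+" else revcomp(seq.sequence)
        # pad so a stop codon starting at position (L-1) + L is fully in view
        scan_seq = s + s + s[:3] if seq.circular else s
        for atg, stop, nt_len, terminated in _scan_frames(
            scan_seq, limit=L, cap=L, min_nt=min_nt
        ):
            if not terminated:
                if seq.circular or not include_truncated:
                    continue
            # Deduplicate circular ORFs by the circular identity of their stop.
            if terminated:
                key = (strand, stop % L if seq.circular else stop)
            else:
                key = (strand, "end", atg % 3)
            prev = results.get(key)
            if prev is not None and prev[1] >= nt_len:
                continue
            if prev is None:
                order.append(key)
            results[key] = (atg, nt_len, terminated)

    orfs = []
    for key in order:
        strand = key[0]
        atg, nt_len, terminated = results[key]
        a0 = atg % L
        end0 = (atg + nt_len - 1) % L
        wraps = seq.circular and (atg + nt_len - 1) >= L
        if strand == "+":
            start, end = a0 + 1, end0 + 1
            nt = _extract(seq.sequence, a0, nt_len, seq.circular)
        else:
            # position q on the reverse strand maps to plus position L-1-q
            start, end = L - a0, L - end0
            nt = _extract(revcomp(seq.sequence), a0, nt_len, seq.circular)
        aa = translate(nt) if terminated else translate(nt).rstrip()
        orfs.append(
            OrfRecord(
                orf_id="",
                contig_id=seq.id,
                start=start,
                end=end,
                strand=strand,
                nt_sequence=nt,
                aa_sequence=aa,
                truncated=not terminated,
                wraps_origin=wraps,
            )
        )
    orfs.sort(key=lambda o: (min(o.start, o.end), o.strand == "-", -o.nt_length))
    for i, o in enumerate(orfs, 1):
        o.orf_id = f"{seq.id}_orf{i:05d}"
    return orfs


def _extract(s: str, start0: int, length: int, circular: bool) -> str:
    if start0 + length <= len(s):
        return s[start0 : start0 + length]
    if not circular:
        raise ValueError("ORF exceeds linear contig")
    out = s[start0:] + s
    return out[:length]


def mean_hydropathy(aa_sequence: str) -> float:
    return sum(KYTE_DOOLITTLE[a] for a in aa_sequence) / len(aa_sequence)


def tm_segments(
    aa_sequence: str, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int, float]]:
    """Maximal segments covered by windows of mean hydropathy >= threshold.

    Returns (start_aa, end_aa, peak_window_mean) with 1-based inclusive amino
    acid coordinates; sequences shorter than ``window`` yield an empty list.
    This is a deliberately simple hydropathy scan, not an HMM; it is used only
    in the optional transcript-filter path, never in the four-criterion screen.
    """
    n = len(aa_sequence)
    if n < window:
        return []
    scores = [KYTE_DOOLITTLE[a] for a in aa_sequence]
    hits = []
    acc = sum(scores[:window])
    if acc / window >= threshold:
        hits.append((0, acc / window))
    for i in range(1, n - window + 1):
        acc += scores[i + window - 1] - scores[i - 1]
        if acc / window >= threshold:
            hits.append((i, acc / window))
    segments: list[tuple[int, int, float]] = []
    for i, mean in hits:
        lo, hi = i + 1, i + window
        if segments and lo <= segments[-1][1] + 1:
            prev = segments[-1]
            segments[-1] = (prev[0], hi, max(prev[2], mean))
        else:
            segments.append((lo, hi, mean))
    return segments
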
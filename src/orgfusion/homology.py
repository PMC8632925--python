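"""Cross-line ORF homology: clustering, similarity search, Type 1-4 labels.

Two complementary notions of "a gene is present in a genome" are implemented,
because the source analyses use both:

* greedy incremental identity clustering (CD-HIT style) over ORF nucleotide
  sequences, used for the Venn-style Type 1-4 classification;
* a seeded, ungapped-extension local similarity search against whole genome
  sequences with Karlin-Altschul expectation values (database size = subject
  length), used for the presence/absence screen and copy-number counting at
  the E <= 1e-50 threshold.

Identity for clustering follows the CD-HIT convention: identical positions in
the best glocal alignment divided by the length of the shorter sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib

from .records import GenomeRecord, OrfRecord, SequenceRecord, revcomp

# Published ungapped Karlin-Altschul parameters for the +1/-2 nucleotide
# scoring scheme (uniform composition); recorded in every hit for
# reproducibility.
MATCH_SCORE = 1
MISMATCH_SCORE = -2
KA_LAMBDA = 1.28
KA_K = 0.46

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence.

    The shorter sequence is aligned glocally (it may fall anywhere inside the
    longer one), so a perfect substring scores identity 1.0.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="path")
    matches = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        if op == "=":
            matches += int(n)
    return matches / len(short)


@dataclass
class ClusterAssignment:
    """One cluster of homologous ORFs across lines."""

    cluster_id: str
    representative_id: str
    member_ids: list[str]
    member_lines: list[str]
    identity_threshold: float

    def lines_present(self) -> set[str]:
        return set(self.member_lines)


def greedy_cluster(
    orfs: Iterable[OrfRecord], identity_threshold: float = 0.9
) -> list[ClusterAssignment]:
    """CD-HIT-style greedy incremental clustering of ORF nucleotide sequences.

    Sequences are processed longest-first (ties broken by lexicographic
    orf_id, which makes the partition permutation-invariant) and each joins
    the first existing cluster whose representative it matches at
    >= identity_threshold, otherwise it seeds a new cluster. Representatives
    are therefore always a longest member of their cluster.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    pool = sorted(orfs, key=lambda o: (-o.nt_length, o.orf_id))
    if not pool:
        raise ValueError("no ORFs to cluster")
    reps: list[OrfRecord] = []
    members: list[list[OrfRecord]] = []
    for orf in pool:
        for i, rep in enumerate(reps):
            if pairwise_identity(orf.nt_sequence, rep.nt_sequence) >= identity_threshold:
                members[i].append(orf)
                break
        else:
            reps.append(orf)
            members.append([orf])
    out = []
    for i, (rep, mem) in enumerate(zip(reps, members), 1):
        out.append(
            ClusterAssignment(
                cluster_id=f"cluster{i:05d}",
                representative_id=rep.orf_id,
                member_ids=[m.orf_id for m in mem],
                member_lines=[m.line_id or "" for m in mem],
                identity_threshold=identity_threshold,
            )
        )
    return out


@dataclass
class SimilarityHit:
    """A local alignment of a query against a subject contig."""

    query_id: str
    subject_id: str
    q_start: int  # 1-based inclusive, on the query as given
    q_end: int
    s_start: int  # 1-based inclusive, plus-strand subject coordinates
    s_end: int
    strand: str   # strand of the subject matched by the query
    score: int
    identity: float
    evalue: float
    length: int
    params: dict = field(default_factory=lambda: {
        "match": MATCH_SCORE, "mismatch": MISMATCH_SCORE,
        "lambda": KA_LAMBDA, "K": KA_K,
    })


def _evalue(score: int, m: int, n: int) -> float:
    # E = K m n exp(-lambda S); guard exp underflow for very high scores.
    x = KA_LAMBDA * score - math.log(KA_K * m * n)
    if x > 700:
        return 0.0
    return math.exp(-x)


def _extend(query: str, subject: str, q0: int, s0: int, k: int, xdrop: int):
    """Ungapped X-drop extension of an exact k-mer seed; returns HSP or None."""
    score = k * MATCH_SCORE
    best = score
    # right extension
    qi, si = q0 + k, s0 + k
    best_right = (q0 + k - 1, s0 + k - 1)
    cur = score
    while qi < len(query) and si < len(subject):
        cur += MATCH_SCORE if query[qi] == subject[si] else MISMATCH_SCORE
        if cur > best:
            best = cur
            best_right = (qi, si)
        if best - cur > xdrop:
            break
        qi += 1
        si += 1
    # left extension
    cur = best
    peak = best
    qi, si = q0 - 1, s0 - 1
    best_left = (q0, s0)
    while qi >= 0 and si >= 0:
        cur += MATCH_SCORE if query[qi] == subject[si] else MISMATCH_SCORE
        if cur > peak:
            peak = cur
            best_left = (qi, si)
        if peak - cur > xdrop:
            break
        qi -= 1
        si -= 1
    q_lo, s_lo = best_left
    q_hi, s_hi = best_right
    length = q_hi - q_lo + 1
    matches = sum(
        1 for a, b in zip(query[q_lo : q_hi + 1], subject[s_lo : s_hi + 1]) if a == b
    )
    score = matches * MATCH_SCORE + (length - matches) * MISMATCH_SCORE
    return q_lo, q_hi, s_lo, s_hi, score, matches / length


_INDEX_CACHE: dict[tuple[int, int, int], dict[str, list[int]]] = {}


def _kmer_index(subj: str, word_size: int) -> dict[str, list[int]]:
    key = (hash(subj), len(subj), word_size)
    cached = _INDEX_CACHE.get(key)
    if cached is not None:
        return cached
    index: dict[str, list[int]] = {}
    for i in range(len(subj) - word_size + 1):
        index.setdefault(subj[i : i + word_size], []).append(i)
    if len(_INDEX_CACHE) > 64:
        _INDEX_CACHE.clear()
    _INDEX_CACHE[key] = index
    return index


def local_similarity_search(
    query: str,
    subject: SequenceRecord | GenomeRecord,
    evalue_max: float = 1e-50,
    word_size: int = 11,
    xdrop: int = 20,
    query_id: str = "query",
    min_length: int = 1,
) -> list[SimilarityHit]:
    """Seeded ungapped local search of a nucleotide query against a subject.

    Both query strands are searched; hits are reported on plus-strand subject
    coordinates with the matched strand. Expectation values use the ungapped
    Karlin-Altschul formula with database size equal to the subject length.
    """
    if isinstance(subject, GenomeRecord):
        hits: list[SimilarityHit] = []
        for contig in subject.contigs:
            hits.extend(
                local_similarity_search(
                    query, contig, evalue_max, word_size, xdrop, query_id, min_length
                )
            )
        hits.sort(key=lambda h: (h.evalue, -h.score))
        return hits

    query = query.upper()
    subj = subject.sequence
    if len(subj) < word_size or len(query) < word_size:
        return []
    index = _kmer_index(subj, word_size)

    m, n = len(query), len(subj)
    hits = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        covered: dict[int, list[tuple[int, int]]] = {}
        for i in range(len(q) - word_size + 1):
            for j in index.get(q[i : i + word_size], ()):
                diag = j - i
                if any(lo <= i <= hi for lo, hi in covered.get(diag, ())):
                    continue
                q_lo, q_hi, s_lo, s_hi, score, ident = _extend(
                    q, subj, i, j, word_size, xdrop
                )
                covered.setdefault(diag, []).append((q_lo, q_hi))
                length = q_hi - q_lo + 1
                if length < min_length:
                    continue
                ev = _evalue(score, m, n)
                if ev > evalue_max:
                    continue
                if strand == "+":
                    qs, qe = q_lo + 1, q_hi + 1
                else:
                    # positions on the reversed query map back to the input
                    qs, qe = len(q) - q_hi, len(q) - q_lo
                hits.append(
                    SimilarityHit(
                        query_id=query_id,
                        subject_id=subject.id,
                        q_start=qs,
                        q_end=qe,
                        s_start=s_lo + 1,
                        s_end=s_hi + 1,
                        strand=strand,
                        score=score,
                        identity=ident,
                        evalue=ev,
                        length=length,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.s_start))
    return hits


def is_present(
    query: str, genome: GenomeRecord, evalue_max: float = 1e-50, **kw
) -> bool:
    """Presence of a sequence in a genome = any hit at E <= evalue_max."""
    for contig in genome.contigs:
        if local_similarity_search(query, contig, evalue_max, **kw):
            return True
    return False


def count_non_overlapping_hits(
    query: str, genome: GenomeRecord, evalue_max: float = 1e-50, **kw
) -> int:
    """Copy number of a gene in a genome: non-overlapping hits at threshold.

    Hits are admitted best-score-first; a hit overlapping an already admitted
    hit on the same subject contig is discarded.
    """
    count = 0
    for contig in genome.contigs:
        hits = local_similarity_search(query, contig, evalue_max, **kw)
        hits.sort(key=lambda h: (-h.score, h.s_start))
        kept: list[tuple[int, int]] = []
        for h in hits:
            lo, hi = min(h.s_start, h.s_end), max(h.s_start, h.s_end)
            if all(hi < a or lo > b for a, b in kept):
                kept.append((lo, hi))
        count += len(kept)
    return count


TYPE_LABELS = ("Type1", "Type2", "Type3", "Type4")


def classify_types(
    clusters: list[ClusterAssignment],
    line_roles: dict[str, str],
) -> tuple[dict[str, str], "pandas.DataFrame"]:
    """Assign Type 1-4 to every CMS ORF from its cluster's presence pattern.

    Pattern over donor roles: (nuclear?, cytoplasmic?) -> (F,F)=Type1 unique,
    (T,F)=Type2 nuclear only, (F,T)=Type3 cytoplasmic only, (T,T)=Type4 both.
    Returns (orf_id -> label) for CMS members plus a per-CMS-line percentage
    table. Clusters with no CMS member are skipped and tallied separately in
    the table attribute ``attrs['clusters_without_cms']``.
    """
    import pandas as pd

    for line, role in line_roles.items():
        if role not in ("cms", "nuclear_donor", "cytoplasmic_donor", "fertile_relative"):
            raise ValueError(f"unknown role {role!r} for line {line!r}")
    cms_lines = sorted(l for l, r in line_roles.items() if r == "cms")
    if not cms_lines:
        raise ValueError("no CMS line among line_roles")

    labels: dict[str, str] = {}
    counts = {line: {t: 0 for t in TYPE_LABELS} for line in cms_lines}
    skipped = 0
    for cl in clusters:
        roles = {line_roles.get(line) for line in cl.lines_present()}
        has_nuc = "nuclear_donor" in roles
        has_cyt = "cytoplasmic_donor" in roles
        label = {
            (False, False): "Type1",
            (True, False): "Type2",
            (False, True): "Type3",
            (True, True): "Type4",
        }[(has_nuc, has_cyt)]
        any_cms = False
        for orf_id, line in zip(cl.member_ids, cl.member_lines):
            if line_roles.get(line) == "cms":
                labels[orf_id] = label
                counts[line][label] += 1
                any_cms = True
        if not any_cms:
            skipped += 1

    rows = []
    for line in cms_lines:
        total = sum(counts[line].values())
        row = {"line": line, "n_orfs": total}
        for t in TYPE_LABELS:
            row[t] = counts[line][t]
            row[f"{t}_pct"] = 100.0 * counts[line][t] / total if total else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["clusters_without_cms"] = skipped
    return labels, table


def type_positional_map(
    labels: dict[str, str], orfs: Iterable[OrfRecord]
) -> "pandas.DataFrame":
    """Ordered (line, contig, position, type) table for positional plotting.

    Positions are ORF start coordinates; rows are sorted by (contig, start)
    so the output is deterministic.
    """
    import pandas as pd

    rows = []
    for o in orfs:
        if o.orf_id in labels:
            rows.append(
                {
                    "line": o.line_id or "",
                    "contig": o.contig_id,
                    "start": o.start,
                    "strand": o.strand,
                    "orf_id": o.orf_id,
                    "type": labels[o.orf_id],
                }
            )
    df = pd.DataFrame(
        rows, columns=["line", "contig", "start", "strand", "orf_id", "type"]
    )
    return df.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
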
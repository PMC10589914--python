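"""Sequence utilities: BLAST tabular parsing, hit filtering, PIR output.

Homology-search results (standard 12-column BLAST tabular output) are read
into :class:`BlastHit` records and filtered on E-value, query coverage,
percent identity and, optionally, the Rost curve of significant sequence
identity — the length-dependent identity threshold

    p(L) = n + 480 * L^(-0.32 * (1 + exp(-L / 1000)))

above which an alignment of length L is considered a safe homology-modeling
template (``n`` shifts the curve; n = 5 is a common conservative choice).

Accepted query/template pairs can be written as PIR alignments in the
dialect consumed by comparative-modeling software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

__all__ = [
    "BlastHit", "HitFilter", "parse_blast_tabular", "rost_threshold",
    "filter_hits", "write_pir", "parse_pir",
]


@dataclass
class BlastHit:
    """One alignment record from 12-column BLAST tabular output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class HitFilter:
    """Thresholds for hit selection; Rost filtering is opt-in."""

    max_evalue: float = math.inf
    min_coverage: float = 0.0   # fraction of the query length, [0, 1]
    min_identity: float = 0.0   # percent
    use_rost: bool = False
    rost_n: int = 5


def parse_blast_tabular(source: Union[str, Iterable[str]]) -> list[BlastHit]:
    """Parse standard 12-column tab-separated BLAST output (outfmt 6/7).

    Lines beginning with '#' are comments and skipped; records are returned
    in file order.
    """
    lines = source.splitlines() if isinstance(source, str) else source
    hits: list[BlastHit] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate whitespace-separated output
            fields = line.split()
        if len(fields) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            hits.append(BlastHit(
                query_id=fields[0], subject_id=fields[1],
                pct_identity=float(fields[2]), aln_length=int(fields[3]),
                mismatches=int(fields[4]), gap_opens=int(fields[5]),
                q_start=int(fields[6]), q_end=int(fields[7]),
                s_start=int(fields[8]), s_end=int(fields[9]),
                e_value=float(fields[10]), bit_score=float(fields[11])))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable numeric field ({exc})") from None
    return hits


def rost_threshold(aln_length: int, n: int = 5) -> float:
    """Percent-identity significance threshold for an alignment of length L.

    p(L) = n + 480 * L^(-0.32 * (1 + exp(-L/1000))); strictly decreasing in
    L and decaying toward n for long alignments.
    """
    if aln_length < 1:
        raise ValueError("alignment length must be at least 1")
    L = float(aln_length)
    return n + 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))


def filter_hits(hits: list[BlastHit], f: HitFilter, query_length: int) -> list[BlastHit]:
    """Hits passing every enabled threshold, in their original order.

    Coverage is measured on the query: (q_end - q_start + 1) / query_length.
    With ``use_rost``, a hit must additionally reach the Rost threshold for
    its own alignment length.
    """
    if query_length < 1:
        raise ValueError("query_length must be at least 1")
    kept = []
    for h in hits:
        if h.e_value > f.max_evalue:
            continue
        if h.query_span / query_length < f.min_coverage:
            continue
        if h.pct_identity < f.min_identity:
            continue
        if f.use_rost and h.pct_identity < rost_threshold(h.aln_length, f.rost_n):
            continue
        kept.append(h)
    return kept


def _wrap60(seq: str) -> list[str]:
    return [seq[i:i + 60] for i in range(0, len(seq), 60)]


def write_pir(query_id: str, query_seq: str, template_id: str, template_seq: str,
              template_chain: str = "A",
              template_start: Union[int, str] = 1,
              template_end: Union[int, str] = 1) -> str:
    """Write one query/template alignment as two PIR entries.

    Sequences must be equal-length aligned strings ('-' for gaps).  The
    template entry carries the ``structureX`` description pointing at the
    template chain and residue range; the query entry is a plain
    ``sequence`` record.  Bodies are wrapped at 60 characters and terminated
    with '*'.
    """
    if len(query_seq) != len(template_seq):
        raise ValueError("aligned sequences must have equal length")
    if not query_seq:
        raise ValueError("empty alignment")
    for seq in (query_seq, template_seq):
        if "*" in seq:
            raise ValueError("'*' is the PIR terminator and may not appear in a sequence")
    lines: list[str] = []
    lines.append(f">P1;{template_id}")
    lines.append(f"structureX:{template_id}:{template_start}:{template_chain}"
                 f":{template_end}:{template_chain}::::")
    body = _wrap60(template_seq)
    body[-1] += "*"
    lines.extend(body)
    lines.append(f">P1;{query_id}")
    lines.append(f"sequence:{query_id}::::::::")
    body = _wrap60(query_seq)
    body[-1] += "*"
    lines.extend(body)
    return "\n".join(lines) + "\n"


def parse_pir(text: str) -> list[dict]:
    """Minimal PIR reader: entries of header, description, '*'-terminated body.

    Returns one dict per entry with ``id``, ``description`` and ``sequence``
    keys; used to validate and round-trip the writer's output.
    """
    entries: list[dict] = []
    current: dict | None = None
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith(">P1;"):
            if current is not None:
                raise ValueError(f"entry {current['id']!r} not terminated with '*'")
            current = {"id": line[4:].strip(), "description": None}
            body = []
        elif current is None:
            if line.strip():
                raise ValueError("sequence data before any '>P1;' header")
        elif current["description"] is None:
            current["description"] = line.strip()
        else:
            body.append(line.strip())
            if line.strip().endswith("*"):
                current["sequence"] = "".join(body)[:-1]
                entries.append(current)
                current = None
    if current is not None:
        raise ValueError(f"entry {current['id']!r} not terminated with '*'")
    return entries
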
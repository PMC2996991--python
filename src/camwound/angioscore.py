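"""Literature keyword scanning: the per-gene "Angioscore".

Each gene's Angioscore is the number of its linked literature abstracts that
mention at least one angiogenesis-related keyword.  Matching is
case-insensitive substring matching, so the stem "endoth" catches both
"endothelial" and "endothelium"; both -is- and -iz- spellings of
neovascularisation are in the default set.  An occurrence-counting mode
(total keyword hits rather than abstracts-with-any-hit) is available behind
the ``unit`` flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

DEFAULT_KEYWORDS = (
    "angiogenic",
    "angiogenesis",
    "neovascularisation",
    "neovascularization",
    "vasculogenesis",
    "vascular",
    "VEGF",
    "hypoxia",
    "endoth",
)


@dataclass(frozen=True)
class KeywordSet:
    """Ordered, case-insensitive substring patterns."""

    patterns: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("keyword set must be non-empty")
        if any(not p for p in self.patterns):
            raise ValueError("keywords must be non-empty strings")

    @property
    def lowered(self) -> tuple[str, ...]:
        return tuple(p.lower() for p in self.patterns)


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract linked to one or more gene symbols."""

    abstract_id: str
    gene_symbols: frozenset[str]
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"abstract {self.abstract_id!r} has empty text")


def contains_angio_keyword(text: str, keywords: KeywordSet | None = None) -> bool:
    """True iff any keyword occurs in ``text`` (case-insensitive substring)."""
    keywords = keywords or KeywordSet()
    lowered = text.lower()
    return any(k in lowered for k in keywords.lowered)


def keyword_occurrences(text: str, keywords: KeywordSet | None = None) -> int:
    """Total keyword occurrence count (each keyword counted independently)."""
    keywords = keywords or KeywordSet()
    lowered = text.lower()
    return sum(lowered.count(k) for k in keywords.lowered)


def compute_angioscore(
    gene_symbol: str,
    corpus: list[AbstractRecord],
    keywords: KeywordSet | None = None,
    unit: str = "abstracts",
) -> int:
    """Angioscore of one gene over a corpus.

    ``unit="abstracts"`` (default) counts linked abstracts containing at
    least one keyword; ``unit="occurrences"`` sums keyword occurrences over
    linked abstracts.  Genes with no linked abstracts score 0.
    """
    if unit not in ("abstracts", "occurrences"):
        raise ValueError("unit must be 'abstracts' or 'occurrences'")
    keywords = keywords or KeywordSet()
    score = 0
    for record in corpus:
        if gene_symbol not in record.gene_symbols:
            continue
        if unit == "abstracts":
            score += int(contains_angio_keyword(record.text, keywords))
        else:
            score += keyword_occurrences(record.text, keywords)
    return score


def angioscore_table(
    genes,
    corpus: list[AbstractRecord],
    keywords: KeywordSet | None = None,
    unit: str = "abstracts",
) -> pd.Series:
    """Angioscores for a gene list, as a Series indexed by gene symbol."""
    keywords = keywords or KeywordSet()
    scores = {g: 0 for g in genes}
    wanted = set(scores)
    for record in corpus:
        hit = None
        for g in record.gene_symbols & wanted:
            if hit is None:
                if unit == "abstracts":
                    hit = int(contains_angio_keyword(record.text, keywords))
                else:
                    hit = keyword_occurrences(record.text, keywords)
            scores[g] += hit
    return pd.Series(scores, name="angioscore", dtype=int)


def read_corpus(path) -> list[AbstractRecord]:
    """Load a corpus from TSV (abstract_id, pipe-separated genes, text) or JSON lines."""
    path = str(path)
    records = []
    if path.endswith((".jsonl", ".json")):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append(
                    AbstractRecord(
                        str(obj["abstract_id"]),
                        frozenset(obj["gene_symbols"]),
                        str(obj["text"]),
                    )
                )
        return records
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["abstract_id", "gene_symbols", "text"], dtype=str
    )
    for row in df.itertuples():
        records.append(
            AbstractRecord(
                str(row.abstract_id),
                frozenset(str(row.gene_symbols).split("|")),
                str(row.text),
            )
        )
    return records


def write_corpus(corpus: list[AbstractRecord], path) -> None:
    with open(path, "w") as fh:
        for r in corpus:
            genes = "|".join(sorted(r.gene_symbols))
            fh.write(f"{r.abstract_id}\t{genes}\t{r.text}\n")
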
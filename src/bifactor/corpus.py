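"""Corpus data model and flat-file I/O.

A corpus is the joined universe of five tables — documents, mentions,
citations, biobanks, funding — from which every downstream analysis
(impact scoring, hidden citations, locality, networks) is computed.

File dialect
------------
Tables are plain CSV with a fixed column order.  List-valued cells use a
``|`` separator; pair-valued entries (affiliations as institution/country,
MeSH conditions as condition/disease-category) separate their two halves
with ``:``, so institution ids, country codes and condition ids must not
contain ``:`` or ``|``.  Documents may alternatively be supplied as JSON
lines (``documents.jsonl``) with the same field names, which avoids the
separator restriction.  Country codes are ISO 3166-1 alpha-2; institution
ids are opaque strings matched exactly.

A corpus directory contains::

    corpus.yaml    # {"reference_year": <int>} plus optional path overrides
    documents.csv  (or documents.jsonl)
    mentions.csv
    citations.csv
    biobanks.csv
    funding.csv
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DOC_TYPES = ("publication", "grant", "patent", "clinical_trial", "policy")
MENTION_LOCATIONS = ("title", "abstract", "acknowledgments")

#: The 14 biobank characteristics used by the feature regression, in
#: canonical column order.  All enter as binary/ordinal class indicators
#: (e.g. ``sample_size_large`` is a top-decile cohort-size flag,
#: ``pi_prestige`` a top-decile PI citation flag).
FEATURE_NAMES = (
    "sample_size_large",
    "open_data_index",
    "pi_prestige",
    "population_based",
    "genetic_markers",
    "gwas",
    "whole_genome_sequencing",
    "gene_environment",
    "registries",
    "surveys",
    "follow_up",
    "medical_records",
    "hospital_based",
    "general_purpose",
)

_YEAR_MIN, _YEAR_MAX = 1800, 2200


class CorpusValidationError(ValueError):
    """Raised when a corpus violates a structural invariant."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


@dataclass
class Document:
    id: str
    doc_type: str
    year: int
    author_ids: list[str] = field(default_factory=list)
    affiliations: list[tuple[str, str]] = field(default_factory=list)
    mesh_conditions: list[tuple[str, str]] = field(default_factory=list)
    rcdc_categories: list[str] = field(default_factory=list)


@dataclass
class Mention:
    document_id: str
    biobank_id: str
    location: str = "abstract"


@dataclass
class CitationEdge:
    citing_id: str
    cited_id: str


@dataclass
class Biobank:
    id: str
    name: str
    establishment_year: int
    host_institution: str
    host_country: str
    reference_paper_ids: list[str] = field(default_factory=list)
    pi_ids: list[str] = field(default_factory=list)
    team_ids: list[str] = field(default_factory=list)
    features: dict[str, float] = field(default_factory=dict)


@dataclass
class FundingCategoryRecord:
    rcdc_category: str
    mean_annual_funding: float


@dataclass
class Violation:
    table: str
    row: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"[{self.table}] row {self.row}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row: object, message: str) -> None:
        self.violations.append(Violation(table, str(row), message))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise CorpusValidationError(self)

    def __str__(self) -> str:
        if self.ok:
            return "corpus valid (0 violations)"
        head = "\n".join(str(v) for v in self.violations[:20])
        extra = len(self.violations) - 20
        if extra > 0:
            head += f"\n... and {extra} more"
        return f"{len(self.violations)} violation(s):\n{head}"


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    citations: list[CitationEdge] = field(default_factory=list)
    biobanks: list[Biobank] = field(default_factory=list)
    funding: list[FundingCategoryRecord] = field(default_factory=list)
    reference_year: int = 2024

    # -- lookup helpers (rebuilt on demand; corpora are treated as frozen
    #    after construction, mutate-and-revalidate workflows should call
    #    invalidate_caches) --

    def __post_init__(self) -> None:
        self._doc_index: dict[str, Document] | None = None
        self._bank_index: dict[str, Biobank] | None = None
        self._mentions_by_bank: dict[str, list[Mention]] | None = None

    def invalidate_caches(self) -> None:
        self._doc_index = None
        self._bank_index = None
        self._mentions_by_bank = None

    @property
    def doc_index(self) -> dict[str, Document]:
        if self._doc_index is None:
            self._doc_index = {d.id: d for d in self.documents}
        return self._doc_index

    @property
    def bank_index(self) -> dict[str, Biobank]:
        if self._bank_index is None:
            self._bank_index = {b.id: b for b in self.biobanks}
        return self._bank_index

    @property
    def mentions_by_bank(self) -> dict[str, list[Mention]]:
        if self._mentions_by_bank is None:
            idx: dict[str, list[Mention]] = {b.id: [] for b in self.biobanks}
            for m in self.mentions:
                idx.setdefault(m.biobank_id, []).append(m)
            self._mentions_by_bank = idx
        return self._mentions_by_bank

    def mentioning_documents(self, biobank_id: str, doc_types=None) -> list[Document]:
        """Distinct documents mentioning ``biobank_id``, optionally filtered by type."""
        docs = self.doc_index
        out, seen = [], set()
        for m in self.mentions_by_bank.get(biobank_id, []):
            d = docs.get(m.document_id)
            if d is None or d.id in seen:
                continue
            if doc_types is not None and d.doc_type not in doc_types:
                continue
            seen.add(d.id)
            out.append(d)
        return out

    def equals(self, other: "Corpus") -> bool:
        """Field-by-field equality (caches excluded)."""
        return (
            self.documents == other.documents
            and self.mentions == other.mentions
            and self.citations == other.citations
            and self.biobanks == other.biobanks
            and self.funding == other.funding
            and self.reference_year == other.reference_year
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_corpus(c: Corpus) -> ValidationReport:
    """Check every structural invariant; an empty report means a valid corpus."""
    rep = ValidationReport()
    doc_ids: set[str] = set()
    for d in c.documents:
        if d.id in doc_ids:
            rep.add("documents", d.id, "duplicate document id")
        doc_ids.add(d.id)
        if d.doc_type not in DOC_TYPES:
            rep.add("documents", d.id, f"unknown doc_type {d.doc_type!r}")
        if not (_YEAR_MIN <= int(d.year) <= _YEAR_MAX):
            rep.add("documents", d.id, f"year {d.year} outside plausible range")
        if d.doc_type != "publication":
            if d.author_ids:
                rep.add("documents", d.id, "non-publication with author_ids")
            if d.mesh_conditions:
                rep.add("documents", d.id, "non-publication with mesh_conditions")
            if d.rcdc_categories:
                rep.add("documents", d.id, "non-publication with rcdc_categories")

    bank_ids: set[str] = set()
    for b in c.biobanks:
        if b.id in bank_ids:
            rep.add("biobanks", b.id, "duplicate biobank id")
        bank_ids.add(b.id)
        if b.establishment_year > c.reference_year:
            rep.add("biobanks", b.id,
                    f"establishment_year {b.establishment_year} after reference_year {c.reference_year}")
        if not set(b.pi_ids) <= set(b.team_ids):
            rep.add("biobanks", b.id, "pi_ids not a subset of team_ids")
        missing = [f for f in FEATURE_NAMES if f not in b.features or b.features[f] is None]
        if missing:
            rep.add("biobanks", b.id, f"missing features: {', '.join(missing)}")
        for rid in b.reference_paper_ids:
            if rid not in doc_ids:
                rep.add("biobanks", b.id, f"reference paper {rid!r} not in documents")

    seen_pairs: set[tuple[str, str]] = set()
    for i, m in enumerate(c.mentions):
        if m.document_id not in doc_ids:
            rep.add("mentions", i, f"unknown document_id {m.document_id!r}")
        if m.biobank_id not in bank_ids:
            rep.add("mentions", i, f"unknown biobank_id {m.biobank_id!r}")
        if m.location not in MENTION_LOCATIONS:
            rep.add("mentions", i, f"unknown location {m.location!r}")
        pair = (m.document_id, m.biobank_id)
        if pair in seen_pairs:
            rep.add("mentions", i, f"duplicate mention pair {pair}")
        seen_pairs.add(pair)

    seen_edges: set[tuple[str, str]] = set()
    for i, e in enumerate(c.citations):
        if e.citing_id == e.cited_id:
            rep.add("citations", i, f"self-loop on {e.citing_id!r}")
        if e.citing_id not in doc_ids:
            rep.add("citations", i, f"unknown citing_id {e.citing_id!r}")
        if e.cited_id not in doc_ids:
            rep.add("citations", i, f"unknown cited_id {e.cited_id!r}")
        edge = (e.citing_id, e.cited_id)
        if edge in seen_edges:
            rep.add("citations", i, f"duplicate citation edge {edge}")
        seen_edges.add(edge)

    seen_cat: set[str] = set()
    for i, f in enumerate(c.funding):
        if f.rcdc_category in seen_cat:
            rep.add("funding", i, f"duplicate category {f.rcdc_category!r}")
        seen_cat.add(f.rcdc_category)
        if f.mean_annual_funding < 0:
            rep.add("funding", i, "negative funding")

    return rep


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _join(items) -> str:
    return "|".join(items)


def _join_pairs(pairs) -> str:
    return "|".join(f"{a}:{b}" for a, b in pairs)


def _split(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return str(cell).split("|")


def _split_pairs(cell: object) -> list[tuple[str, str]]:
    out = []
    for item in _split(cell):
        a, _, b = item.partition(":")
        out.append((a, b))
    return out


_DOC_COLS = ["id", "doc_type", "year", "author_ids", "affiliations",
             "mesh_conditions", "rcdc_categories"]
_BANK_COLS = ["id", "name", "establishment_year", "host_institution",
              "host_country", "reference_paper_ids", "pi_ids", "team_ids",
              *FEATURE_NAMES]


def documents_to_frame(docs: list[Document]) -> pd.DataFrame:
    rows = [
        {
            "id": d.id,
            "doc_type": d.doc_type,
            "year": d.year,
            "author_ids": _join(d.author_ids),
            "affiliations": _join_pairs(d.affiliations),
            "mesh_conditions": _join_pairs(d.mesh_conditions),
            "rcdc_categories": _join(d.rcdc_categories),
        }
        for d in docs
    ]
    return pd.DataFrame(rows, columns=_DOC_COLS)


def write_corpus(c: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write the five tables plus ``corpus.yaml`` to ``out_dir``.

    Rows are emitted in a canonical sort order so that identical corpora
    produce identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    docs = documents_to_frame(sorted(c.documents, key=lambda d: d.id))
    paths["documents"] = out / "documents.csv"
    docs.to_csv(paths["documents"], index=False, lineterminator="\n")

    mentions = pd.DataFrame(
        [{"document_id": m.document_id, "biobank_id": m.biobank_id, "location": m.location}
         for m in sorted(c.mentions, key=lambda m: (m.document_id, m.biobank_id))],
        columns=["document_id", "biobank_id", "location"],
    )
    paths["mentions"] = out / "mentions.csv"
    mentions.to_csv(paths["mentions"], index=False, lineterminator="\n")

    cits = pd.DataFrame(
        [{"citing_id": e.citing_id, "cited_id": e.cited_id}
         for e in sorted(c.citations, key=lambda e: (e.citing_id, e.cited_id))],
        columns=["citing_id", "cited_id"],
    )
    paths["citations"] = out / "citations.csv"
    cits.to_csv(paths["citations"], index=False, lineterminator="\n")

    banks = pd.DataFrame(
        [
            {
                "id": b.id,
                "name": b.name,
                "establishment_year": b.establishment_year,
                "host_institution": b.host_institution,
                "host_country": b.host_country,
                "reference_paper_ids": _join(b.reference_paper_ids),
                "pi_ids": _join(b.pi_ids),
                "team_ids": _join(b.team_ids),
                **{f: b.features.get(f) for f in FEATURE_NAMES},
            }
            for b in sorted(c.biobanks, key=lambda b: b.id)
        ],
        columns=_BANK_COLS,
    )
    paths["biobanks"] = out / "biobanks.csv"
    banks.to_csv(paths["biobanks"], index=False, lineterminator="\n")

    fund = pd.DataFrame(
        [{"rcdc_category": f.rcdc_category, "mean_annual_funding": f.mean_annual_funding}
         for f in sorted(c.funding, key=lambda f: f.rcdc_category)],
        columns=["rcdc_category", "mean_annual_funding"],
    )
    paths["funding"] = out / "funding.csv"
    fund.to_csv(paths["funding"], index=False, lineterminator="\n")

    meta = out / "corpus.yaml"
    meta.write_text(yaml.safe_dump({"reference_year": int(c.reference_year)}))
    paths["meta"] = meta
    return paths


def _read_documents(path: Path) -> list[Document]:
    if path.suffix == ".jsonl":
        docs = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                docs.append(Document(
                    id=str(rec["id"]),
                    doc_type=rec["doc_type"],
                    year=int(rec["year"]),
                    author_ids=[str(a) for a in rec.get("author_ids", [])],
                    affiliations=[tuple(a) for a in rec.get("affiliations", [])],
                    mesh_conditions=[tuple(m) for m in rec.get("mesh_conditions", [])],
                    rcdc_categories=list(rec.get("rcdc_categories", [])),
                ))
        return docs
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Document(
            id=row["id"],
            doc_type=row["doc_type"],
            year=int(row["year"]),
            author_ids=_split(row["author_ids"]),
            affiliations=_split_pairs(row["affiliations"]),
            mesh_conditions=_split_pairs(row["mesh_conditions"]),
            rcdc_categories=_split(row["rcdc_categories"]),
        )
        for row in df.to_dict("records")
    ]


def load_corpus(path: str | Path, reference_year: int | None = None) -> Corpus:
    """Load and validate a corpus.

    ``path`` is either a corpus directory (standard file names, metadata in
    ``corpus.yaml``) or a YAML config file mapping table names to paths and
    giving ``reference_year``.  Duplicate mention pairs are collapsed with a
    warning; any other invariant violation raises
    :class:`CorpusValidationError` naming the offending table and row.
    """
    path = Path(path)
    if path.is_dir():
        cfg: dict = {}
        meta = path / "corpus.yaml"
        if meta.exists():
            cfg = yaml.safe_load(meta.read_text()) or {}
        base = path
    else:
        cfg = yaml.safe_load(path.read_text()) or {}
        base = path.parent

    def table_path(name: str, default: str) -> Path:
        p = Path(cfg.get("paths", {}).get(name, default))
        return p if p.is_absolute() else base / p

    doc_path = table_path("documents", "documents.csv")
    if not doc_path.exists() and doc_path.suffix == ".csv":
        alt = doc_path.with_suffix(".jsonl")
        if alt.exists():
            doc_path = alt
    for p in [doc_path, table_path("mentions", "mentions.csv"),
              table_path("citations", "citations.csv"),
              table_path("biobanks", "biobanks.csv"),
              table_path("funding", "funding.csv")]:
        if not p.exists():
            raise FileNotFoundError(f"corpus table missing: {p}")

    documents = _read_documents(doc_path)

    mdf = pd.read_csv(table_path("mentions", "mentions.csv"), dtype=str,
                      keep_default_na=False)
    n_raw = len(mdf)
    mdf = mdf.drop_duplicates(subset=["document_id", "biobank_id"])
    if len(mdf) < n_raw:
        warnings.warn(f"collapsed {n_raw - len(mdf)} duplicate mention pair(s)",
                      stacklevel=2)
    mentions = [Mention(r["document_id"], r["biobank_id"], r["location"])
                for r in mdf.to_dict("records")]

    cdf = pd.read_csv(table_path("citations", "citations.csv"), dtype=str,
                      keep_default_na=False)
    citations = [CitationEdge(r["citing_id"], r["cited_id"])
                 for r in cdf.to_dict("records")]

    bdf = pd.read_csv(table_path("biobanks", "biobanks.csv"), dtype=str,
                      keep_default_na=False)
    biobanks = []
    for r in bdf.to_dict("records"):
        feats = {}
        for f in FEATURE_NAMES:
            v = r.get(f, "")
            feats[f] = float(v) if v != "" else None
        biobanks.append(Biobank(
            id=r["id"], name=r["name"],
            establishment_year=int(r["establishment_year"]),
            host_institution=r["host_institution"],
            host_country=r["host_country"],
            reference_paper_ids=_split(r["reference_paper_ids"]),
            pi_ids=_split(r["pi_ids"]),
            team_ids=_split(r["team_ids"]),
            features=feats,
        ))

    fdf = pd.read_csv(table_path("funding", "funding.csv"), keep_default_na=False)
    funding = [FundingCategoryRecord(str(r["rcdc_category"]), float(r["mean_annual_funding"]))
               for r in fdf.to_dict("records")]

    ref_year = reference_year if reference_year is not None else int(cfg.get("reference_year", 2024))
    corpus = Corpus(documents=documents, mentions=mentions, citations=citations,
                    biobanks=biobanks, funding=funding, reference_year=ref_year)
    validate_corpus(corpus).raise_if_invalid()
    return corpus
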
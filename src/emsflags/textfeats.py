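"""Comparison featurizers: TF-IDF and concept-embedding vectorization.

TF-IDF weights word tokens by term frequency times smoothed inverse
document frequency, idf(t) = ln((1 + N) / (1 + df(t))) + 1, with L2 row
normalization. Documents are the concatenation of the selected text fields
(all six by default, for parity with the flag featurizer).

Concept vectorization abstracts the UMLS-concept-embedding approach
(Cui2Vec-style) behind a pluggable surface-form lexicon and a concept-id ->
vector table: surfaces found in the chief narrative are mapped to concept
ids and the record vector is the unweighted mean of the matched concepts'
embeddings. No entity linking or disambiguation is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .matrix import FeatureMatrix
from .records import TEXT_FIELDS, Cohort

logger = logging.getLogger(__name__)

TOKEN_PATTERN = r"(?u)\b\w\w+\b"


@dataclass
class TfidfModel:
    """A fitted TF-IDF weighting: vocabulary, idf weights, and parameters."""

    vocabulary: dict
    idf: np.ndarray
    doc_count: int
    params: dict
    fields: tuple
    _vectorizer: TfidfVectorizer = field(repr=False, compare=False)


def _documents(cohort: Cohort, fields) -> list:
    return [rec.text(fields) for rec in cohort]


def fit_tfidf(cohort: Cohort, fields=TEXT_FIELDS, min_df: int = 1) -> TfidfModel:
    """Fit TF-IDF on the concatenated text fields of a training cohort.

    Tokens are lowercased word tokens of at least two characters; terms with
    document frequency below ``min_df`` are dropped.
    """
    fields = tuple(fields)
    docs = _documents(cohort, fields)
    if not any(d.strip() for d in docs):
        raise ValueError("empty corpus: no non-empty documents after concatenation")
    vec = TfidfVectorizer(
        lowercase=True,
        token_pattern=TOKEN_PATTERN,
        min_df=min_df,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    vec.fit(docs)
    return TfidfModel(
        vocabulary=dict(vec.vocabulary_),
        idf=np.asarray(vec.idf_),
        doc_count=len(docs),
        params={
            "lowercase": True,
            "token_pattern": TOKEN_PATTERN,
            "min_df": min_df,
            "norm": "l2",
        },
        fields=fields,
        _vectorizer=vec,
    )


def transform_tfidf(model: TfidfModel, cohort: Cohort) -> FeatureMatrix:
    """Apply a fitted TF-IDF model (training idf) to any cohort.

    Rows are L2-normalized unless identically zero; out-of-vocabulary
    terms are ignored.
    """
    docs = _documents(cohort, model.fields)
    values = model._vectorizer.transform(docs).toarray()
    order = sorted(model.vocabulary, key=model.vocabulary.get)
    names = [f"tfidf__{t}" for t in order]
    return FeatureMatrix(cohort.record_ids, names, values)


# ---------------------------------------------------------------------------
# Concept embeddings


@dataclass
class ConceptLexicon:
    """Surface-form -> concept-id map with longest-match scanning."""

    surfaces: dict
    _pattern: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm = {}
        for s, cid in self.surfaces.items():
            key = " ".join(str(s).lower().split())
            if not key:
                raise ValueError("empty lexicon surface")
            if key in norm and norm[key] != cid:
                raise ValueError(f"conflicting concept ids for surface {key!r}")
            norm[key] = str(cid)
        if not norm:
            raise ValueError("empty lexicon")
        self.surfaces = norm
        alts = []
        for s in sorted(norm, key=len, reverse=True):
            body = r"\s+".join(re.escape(w) for w in s.split())
            alts.append(rf"(?<!\w){body}(?!\w)")
        self._pattern = re.compile("|".join(alts), re.IGNORECASE)

    @classmethod
    def from_tsv(cls, path) -> "ConceptLexicon":
        surfaces = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                surface, cid = line.split("\t")
                surfaces[surface] = cid
        return cls(surfaces)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for s in sorted(self.surfaces):
                fh.write(f"{s}\t{self.surfaces[s]}\n")


@dataclass
class EmbeddingTable:
    """Concept-id -> dense vector map; all vectors share one dimension."""

    vectors: dict
    dimension: int = 0

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("empty embedding table")
        vecs = {}
        dim = None
        for cid, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if dim is None:
                dim = v.shape[0]
            if v.shape != (dim,):
                raise ValueError(f"vector for {cid!r} has wrong dimension")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite embedding for {cid!r}")
            vecs[str(cid)] = v
        self.vectors = vecs
        self.dimension = int(dim)

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingTable":
        vectors = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0].strip():
                    continue
                vectors[parts[0]] = [float(x) for x in parts[1:]]
        return cls(vectors)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for cid in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[cid])
                fh.write(f"{cid}\t{vals}\n")


def extract_concepts(text: str, lexicon: ConceptLexicon) -> list:
    """Scan text for lexicon surfaces; emit concept ids in match order.

    Case-insensitive, longest-match-first, non-overlapping, left-to-right;
    duplicates are preserved.
    """
    out = []
    for m in lexicon._pattern.finditer(text):
        key = " ".join(m.group(0).lower().split())
        out.append(lexicon.surfaces[key])
    return out


def vectorize_narrative(
    cohort: Cohort,
    lexicon: ConceptLexicon,
    embeddings: EmbeddingTable,
    field_name: str = "chief_narrative",
) -> FeatureMatrix:
    """Embed one text field (the chief narrative by default) per record.

    The row vector is the unweighted mean of the embeddings of matched
    concepts, with multiplicity; records with no match get a zero vector.
    Concepts absent from the embedding table are skipped (count logged).
    """
    d = embeddings.dimension
    values = np.zeros((len(cohort), d))
    skipped = 0
    for i, rec in enumerate(cohort):
        cids = extract_concepts(getattr(rec, field_name), lexicon)
        vecs = []
        for cid in cids:
            if cid in embeddings.vectors:
                vecs.append(embeddings.vectors[cid])
            else:
                skipped += 1
        if vecs:
            values[i] = np.mean(vecs, axis=0)
    if skipped:
        logger.info("vectorize_narrative: skipped %d concept mentions missing "
                    "from the embedding table", skipped)
    names = [f"concept__{j:03d}" for j in range(d)]
    return FeatureMatrix(cohort.record_ids, names, values)


def demo_concept_resources(seed: int = 0, dimension: int = 20):
    """A small synthetic lexicon + embedding table for benchmarks and tests.

    Covers the curated opioid/overdose keywords plus a few generic clinical
    surfaces, with seeded Gaussian embeddings. This is a synthetic stand-in
    for an externally licensed concept-embedding release; real resources can
    be supplied as TSV files instead.
    """
    from .flags import OPIOID_TERMS, OVERDOSE_TERMS

    surfaces = list(OPIOID_TERMS) + list(OVERDOSE_TERMS) + [
        "altered mental status",
        "respiratory depression",
        "pinpoint pupils",
        "unresponsive",
        "chest pain",
        "shortness of breath",
        "suicidal ideation",
        "unknown pain pills",
    ]
    lexicon = ConceptLexicon(
        {s: f"C{1000000 + i:07d}" for i, s in enumerate(surfaces)}
    )
    rng = np.random.default_rng(seed)
    vectors = {
        cid: rng.normal(size=dimension)
        for cid in sorted(set(lexicon.surfaces.values()))
    }
    return lexicon, EmbeddingTable(vectors)
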
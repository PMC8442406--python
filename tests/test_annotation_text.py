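import math

import numpy as np
import pandas as pd
import pytest

from oracles import weighted_cosine_by_enumeration
from phagelink.annotation_text import (
    STOPLIST,
    TermCorpus,
    build_annotation,
    build_corpus,
    clean_annotation,
    distance_vs_probability,
    process_annotations,
    read_annotation_tsv,
    tokenize,
    weighted_cosine_distance,
)
from phagelink.evaluation import UNDEFINED


class TestProcessAnnotations:
    def test_hypothetical_majority_becomes_unknown(self):
        raw = ["hypothetical protein", "hypothetical protein", "tail fiber protein"]
        assert process_annotations(raw) == "unknown"

    def test_filler_tokens_removed(self):
        assert process_annotations(["putative tail protein"]) == "tail"

    def test_tie_breaks_lexicographically(self):
        assert process_annotations(["holin", "lysin"]) == "holin"

    def test_clean_lowercases_and_normalizes_whitespace(self):
        assert clean_annotation("Putative  TAIL   Protein") == "tail"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            process_annotations([])


class TestTokenize:
    def test_punctuation_stripped_except_hyphen(self):
        assert tokenize("Tail, fiber; (gp37)") == ["tail", "fiber", "gp37"]
        assert "head-tail" in tokenize("head-tail connector")

    def test_stoplist_symbols_survive_tokenization(self):
        assert tokenize("# protein & partner") == ["#", "protein", "&", "partner"]


class TestBuildCorpus:
    @staticmethod
    def annotations(term_sets):
        return [
            build_annotation(f"V{i}", [" ".join(terms)])
            for i, terms in enumerate(term_sets)
        ]

    def test_ubiquitous_term_weight_zero(self):
        corpus = build_corpus(self.annotations([["tail"], ["tail"]]))
        assert corpus.weight["tail"] == 0.0

    def test_rare_term_weight(self):
        term_sets = [["tail"]] + [["fiber"]] * 9
        corpus = build_corpus(self.annotations(term_sets))
        assert corpus.weight["tail"] == pytest.approx(0.9)

    def test_stoplist_terms_absent(self):
        corpus = build_corpus(self.annotations([["phage", "tail"], ["tail"]]))
        assert "phage" not in corpus.terms and "tail" in corpus.terms

    def test_unannotated_groups_do_not_count_as_documents(self):
        anns = self.annotations([["tail"], ["tail"]]) + [
            build_annotation("U", ["hypothetical protein"])
        ]
        corpus = build_corpus(anns)
        assert corpus.weight["tail"] == 0.0  # 2 of 2 informative docs

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_corpus([build_annotation("U", ["hypothetical protein"])])


class TestWeightedCosineDistance:
    CORPUS = TermCorpus(
        terms=frozenset({"tail", "fiber"}), weight={"tail": 0.5, "fiber": 0.9}
    )

    def test_identical_vectors_zero(self):
        v = {"tail": 2, "fiber": 1}
        assert weighted_cosine_distance(v, v, self.CORPUS) == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        assert weighted_cosine_distance(
            {"tail": 1}, {"fiber": 3}, self.CORPUS
        ) == pytest.approx(1.0)

    def test_two_term_worked_example(self):
        a, b = {"tail": 1, "fiber": 1}, {"tail": 1}
        d = weighted_cosine_distance(a, b, self.CORPUS)
        # independent brute-force evaluation of the same definition
        assert d == pytest.approx(
            weighted_cosine_by_enumeration(a, b, self.CORPUS.weight), abs=1e-12
        )
        assert d == pytest.approx(1 - 0.5 / math.sqrt(0.7), abs=1e-6)
        assert d == pytest.approx(0.4024, abs=5e-5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = {t: int(rng.integers(0, 4)) for t in self.CORPUS.terms}
            b = {t: int(rng.integers(0, 4)) for t in self.CORPUS.terms}
            da = weighted_cosine_distance(a, b, self.CORPUS)
            db = weighted_cosine_distance(b, a, self.CORPUS)
            if da is UNDEFINED:
                assert db is UNDEFINED
            else:
                assert da == pytest.approx(db)
                assert 0.0 <= da <= 1.0

    def test_zero_norm_undefined(self):
        assert weighted_cosine_distance({}, {"tail": 1}, self.CORPUS) is UNDEFINED


class TestDistanceVsProbability:
    @staticmethod
    def annotated(pvog, terms):
        return build_annotation(pvog, [" ".join(terms)] * 3)

    def test_perfect_anticorrelation(self):
        # distance is exactly 1 - probability by construction
        anns = {
            "A": self.annotated("A", ["tail", "fiber", "spike"]),
            "B": self.annotated("B", ["tail", "fiber", "spike"]),
            "C": self.annotated("C", ["portal", "capsid", "head"]),
            "D": self.annotated("D", ["portal", "capsid", "head"]),
            "E": self.annotated("E", ["holin", "lysin", "spanin"]),
            "F": self.annotated("F", ["terminase", "motor", "subunit"]),
        }
        corpus = build_corpus(anns.values())
        rows = []
        for a, b in (("A", "B"), ("C", "D"), ("E", "F"), ("A", "C"), ("B", "F")):
            d = weighted_cosine_distance(
                anns[a].term_vector, anns[b].term_vector, corpus
            )
            rows.append((a, b, 1.0 - d))
        df = pd.DataFrame(rows, columns=["pvog_a", "pvog_b", "probability"])
        r, p, n = distance_vs_probability(df, anns, min_terms=3, corpus=corpus)
        assert r == pytest.approx(-1.0)
        assert n == 5

    def test_independent_probability_uncorrelated(self):
        rng = np.random.default_rng(9)
        vocab = [f"term{i}" for i in range(12)]
        anns = {}
        for i in range(60):
            terms = list(rng.choice(vocab, size=4, replace=False))
            anns[f"V{i}"] = self.annotated(f"V{i}", terms)
        corpus = build_corpus(anns.values())
        names = sorted(anns)
        rows = []
        for _ in range(10_000):
            a, b = rng.choice(names, 2, replace=False)
            rows.append((a, b, float(rng.uniform())))
        df = pd.DataFrame(rows, columns=["pvog_a", "pvog_b", "probability"])
        r, _, n = distance_vs_probability(df, anns, min_terms=3, corpus=corpus)
        assert n == 10_000
        assert abs(r) < 0.1

    def test_min_terms_filter_excludes_sparse_pvogs(self):
        anns = {
            "A": self.annotated("A", ["tail", "fiber"]),  # 2 informative terms
            "B": self.annotated("B", ["portal", "capsid", "head", "major", "minor"]),
            "C": self.annotated("C", ["holin", "lysin", "spanin"]),
        }
        df = pd.DataFrame(
            [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7)],
            columns=["pvog_a", "pvog_b", "probability"],
        )
        with pytest.raises(ValueError, match="eligible"):
            distance_vs_probability(df, anns, min_terms=3)


def test_annotation_tsv_reader(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "pvog_id\tannotation\n"
        "V1\ttail fiber protein\n"
        "V1\ttail fiber protein\n"
        "V1\thypothetical protein\n"
        "V2\thypothetical protein\n"
    )
    anns = read_annotation_tsv(path)
    assert anns["V1"].processed_annotation == "tail fiber"
    assert anns["V1"].is_annotated and not anns["V2"].is_annotated
    assert anns["V1"].informative_term_count == 2


def test_stoplist_contents():
    # the misspelled 'hypothetical' variants and glue words must all be there
    assert {"hypothetical", "putative", "phage", "#", "&"} <= set(STOPLIST)
    assert len(STOPLIST) == len(set(STOPLIST))
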
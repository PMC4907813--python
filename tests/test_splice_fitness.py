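"""Donor/acceptor k-mer scoring: weight-matrix and maxent-table backends."""

import math
from pathlib import Path

import numpy as np
import pytest

from splicepriors import (
    InvalidKmerError,
    Kmer,
    ModelLoadError,
    SiteType,
    WeightMatrixModel,
    load_maxent_tables,
    score_kmer,
    train_weight_matrix,
)

DONOR = SiteType.DONOR
ACCEPTOR = SiteType.ACCEPTOR


def uniform_matrix(site_type):
    return WeightMatrixModel(
        site_type=site_type, probs=np.full((site_type.k, 4), 0.25)
    )


class TestKmer:
    def test_lowercase_is_uppercased(self):
        km = Kmer("cagGTAAGT", DONOR)
        assert km.sequence == "CAGGTAAGT"

    @pytest.mark.parametrize(
        "seq,site_type",
        [
            ("CAGGTAAG", DONOR),  # wrong length
            ("CAGGTAAGT", ACCEPTOR),  # donor length, acceptor type
            ("CAGGTNAGT", DONOR),  # ambiguity code
        ],
    )
    def test_invalid_kmers_rejected(self, seq, site_type):
        with pytest.raises(InvalidKmerError):
            Kmer(seq, site_type)


class TestWeightMatrix:
    def test_background_identical_model_scores_zero(self):
        model = uniform_matrix(DONOR)
        assert score_kmer(model, Kmer("CAGGTAAGT", DONOR)) == 0.0
        assert score_kmer(model, Kmer("ACGTACGTA", DONOR)) == 0.0

    def test_single_informative_position_scores_one_bit(self):
        probs = np.full((9, 4), 0.25)
        probs[4] = [1 / 6, 1 / 6, 0.5, 1 / 6]
        model = WeightMatrixModel(site_type=DONOR, probs=probs)
        # G at the informative position: log2(0.5 / 0.25) = 1 bit
        assert score_kmer(model, Kmer("AAAAGAAAA", DONOR)) == pytest.approx(1.0)

    def test_additivity_over_positions(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=9)
        model = WeightMatrixModel(site_type=DONOR, probs=probs)
        base = "CAGGTAAGT"
        s0 = model.score(base)
        for pos in range(9):
            for alt in "ACGT":
                mutated = base[:pos] + alt + base[pos + 1 :]
                expected_delta = model._log_odds[pos, "ACGT".index(alt)] - (
                    model._log_odds[pos, "ACGT".index(base[pos])]
                )
                assert model.score(mutated) - s0 == pytest.approx(expected_delta)

    def test_site_type_mismatch_rejected(self):
        model = uniform_matrix(DONOR)
        with pytest.raises(InvalidKmerError):
            score_kmer(model, Kmer("A" * 23, ACCEPTOR))

    def test_determinism_bitwise(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=9)
        model = WeightMatrixModel(site_type=DONOR, probs=probs)
        scores = {model.score("CAGGTAAGT") for _ in range(20)}
        assert len(scores) == 1

    def test_model_mean_dominates_background_mean(self):
        # non-negativity of KL divergence, by simulation
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.full(4, 2.0), size=9)
        model = WeightMatrixModel(site_type=DONOR, probs=probs)
        n = 2000
        from_model = [
            "".join(rng.choice(list("ACGT"), p=probs[i]) for i in range(9))
            for _ in range(n)
        ]
        from_bg = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(n)]
        mean_model = np.mean([model.score(s) for s in from_model])
        mean_bg = np.mean([model.score(s) for s in from_bg])
        assert mean_bg <= mean_model

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet(np.ones(4), size=23)
        model = WeightMatrixModel(site_type=ACCEPTOR, probs=probs)
        path = tmp_path / "acc.tsv"
        model.to_tsv(path)
        loaded = WeightMatrixModel.from_tsv(path, ACCEPTOR)
        kmer = "".join(rng.choice(list("ACGT"), size=23))
        assert loaded.score(kmer) == pytest.approx(model.score(kmer), abs=1e-9)


class TestTrainWeightMatrix:
    def test_identical_kmers_with_pseudocount(self):
        kmers = [Kmer("CAGGTAAGT", DONOR)] * 10
        model = train_weight_matrix(kmers, pseudocount=1.0)
        # consensus base probability (10+1)/(10+4) at every position
        for i, b in enumerate("CAGGTAAGT"):
            assert model.probs[i, "ACGT".index(b)] == pytest.approx(11 / 14)

    def test_uniform_column_contributes_zero(self):
        kmers = [Kmer(b + "AGGTAAGT", DONOR) for b in "ACGT"]
        model = train_weight_matrix(kmers, pseudocount=1.0)
        assert np.allclose(model._log_odds[0], 0.0)

    def test_recovers_generating_table(self):
        rng = np.random.default_rng(42)
        truth = rng.dirichlet(np.full(4, 2.0), size=9)
        kmers = [
            Kmer(
                "".join(rng.choice(list("ACGT"), p=truth[i]) for i in range(9)),
                DONOR,
            )
            for _ in range(100)
        ]
        model = train_weight_matrix(kmers, pseudocount=0.5)
        assert np.max(np.abs(model.probs - truth)) < 0.1

    def test_consensus_beats_random_expectation(self):
        rng = np.random.default_rng(1)
        kmers = [Kmer("CAGGTAAGT", DONOR)] * 20
        model = train_weight_matrix(kmers, pseudocount=1.0)
        consensus_score = model.score("CAGGTAAGT")
        random_scores = [
            model.score("".join(rng.choice(list("ACGT"), size=9)))
            for _ in range(200)
        ]
        assert consensus_score > np.mean(random_scores)

    def test_errors(self):
        with pytest.raises(ValueError):
            train_weight_matrix([])
        mixed = [Kmer("A" * 9, DONOR), Kmer("A" * 23, ACCEPTOR)]
        with pytest.raises(ValueError):
            train_weight_matrix(mixed)


# ---------------------------------------------------------------------------
# MaxEntScan-format tables (synthetic table sets written at test time)
# ---------------------------------------------------------------------------

_ACC_FRAG = [(0, 7), (7, 7), (14, 7), (4, 7), (11, 7), (4, 3), (7, 4), (11, 3), (14, 4)]


def write_donor_dir(path: Path, rng) -> np.ndarray:
    table = rng.uniform(0.01, 4.0, size=4**7)
    path.joinpath("me2x5").write_text("\n".join(f"{v:.9g}" for v in table) + "\n")
    return table


def write_acceptor_dir(path: Path, rng) -> list[np.ndarray]:
    tables = []
    for i, (_, ln) in enumerate(_ACC_FRAG, start=1):
        t = rng.uniform(0.01, 4.0, size=4**ln)
        path.joinpath(f"me2x3acc{i}").write_text(
            "\n".join(f"{v:.9g}" for v in t) + "\n"
        )
        tables.append(t)
    return tables


def base4(seq: str) -> int:
    """Independent lexicographic index computation for the oracle."""
    return int(seq.translate(str.maketrans("ACGT", "0123")), 4)


class TestMaxEntTables:
    def test_empty_directory_is_error(self, tmp_path):
        with pytest.raises(ModelLoadError):
            load_maxent_tables(tmp_path)

    def test_negative_entry_is_error(self, tmp_path):
        rng = np.random.default_rng(0)
        table = write_donor_dir(tmp_path, rng)
        table[5] = -1.0
        (tmp_path / "me2x5").write_text("\n".join(f"{v:.9g}" for v in table))
        with pytest.raises(ModelLoadError):
            load_maxent_tables(tmp_path)

    def test_truncated_table_is_error(self, tmp_path):
        (tmp_path / "me2x5").write_text("1.0\n2.0\n")
        with pytest.raises(ModelLoadError, match="me2x5"):
            load_maxent_tables(tmp_path)

    def test_donor_scoring_matches_oracle(self, tmp_path):
        rng = np.random.default_rng(21)
        table = write_donor_dir(tmp_path, rng)
        model = load_maxent_tables(tmp_path)
        assert model.site_type is DONOR
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=9))
            rest = seq[:3] + seq[5:]
            cons = (
                model.cons1[seq[3]]
                * model.cons2[seq[4]]
                / (model.background[seq[3]] * model.background[seq[4]])
            )
            expected = math.log2(cons * table[base4(rest)])
            # tables round-trip through text at ~9 significant digits
            assert model.score(seq) == pytest.approx(expected, abs=1e-6)

    def test_acceptor_scoring_matches_oracle(self, tmp_path):
        rng = np.random.default_rng(22)
        tables = write_acceptor_dir(tmp_path, rng)
        model = load_maxent_tables(tmp_path)
        assert model.site_type is ACCEPTOR
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=23))
            rest = seq[:18] + seq[20:]
            prod = 1.0
            for (start, ln), table, num in zip(
                _ACC_FRAG, tables, [1, 1, 1, 1, 1, 0, 0, 0, 0]
            ):
                v = table[base4(rest[start : start + ln])]
                prod = prod * v if num else prod / v
            cons = (
                model.cons1[seq[18]]
                * model.cons2[seq[19]]
                / (model.background[seq[18]] * model.background[seq[19]])
            )
            expected = math.log2(cons * prod)
            assert model.score(seq) == pytest.approx(expected, abs=1e-6)

    def test_consensus_override_file(self, tmp_path):
        import json

        rng = np.random.default_rng(2)
        write_donor_dir(tmp_path, rng)
        override = {
            "background": {b: 0.25 for b in "ACGT"},
            "cons1": {"A": 0.1, "C": 0.1, "G": 0.7, "T": 0.1},
            "cons2": {"A": 0.1, "C": 0.1, "G": 0.1, "T": 0.7},
        }
        (tmp_path / "consensus.json").write_text(json.dumps(override))
        model = load_maxent_tables(tmp_path)
        assert model.cons1["G"] == 0.7
        assert model.background["A"] == 0.25
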
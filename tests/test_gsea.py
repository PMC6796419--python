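"""Preranked GSEA: the weighted KS walk, permutation null, leading edges."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from crosscontrast.gene_sets import read_gmt, write_gmt
from crosscontrast.gsea import (enrichment_score, preranked_gsea,
                                rank_by_score)


def walk_oracle(scores, hit_mask, p):
    """Exhaustive step-by-step walk, kept deliberately naive."""
    n = len(scores)
    n_hit = sum(hit_mask)
    denom = sum(abs(s) ** p for s, h in zip(scores, hit_mask) if h)
    cum, best, best_i = 0.0, 0.0, 0
    path = []
    for i in range(n):
        if hit_mask[i]:
            cum += (abs(scores[i]) ** p) / denom if denom else 1.0 / n_hit
        else:
            cum -= 1.0 / (n - n_hit)
        path.append(cum)
        if abs(cum) > abs(best):
            best, best_i = cum, i
    return best, path


class TestEnrichmentScore:
    def test_hand_enumerated_five_gene_walk(self):
        ranking = pd.Series([5.0, 4, 3, 2, 1],
                            index=["g1", "g2", "g3", "g4", "g5"])
        es, le = enrichment_score(ranking, {"g1", "g3"}, p=1)
        assert es == pytest.approx(2 / 3)
        assert le == ["g1", "g3"]

    def test_bottom_set_negative_es_tail_leading_edge(self):
        ranking = pd.Series([3.0, 2, 1, -1, -2, -3],
                            index=[f"g{i}" for i in range(6)])
        es, le = enrichment_score(ranking, {"g4", "g5"})
        assert es < 0
        assert set(le) == {"g4", "g5"}

    def test_unweighted_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = 20
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            ranking = pd.Series(scores, index=genes)
            members = set(rng.choice(genes, size=rng.integers(2, 10),
                                     replace=False))
            hit_mask = [g in members for g in genes]
            es, _ = enrichment_score(ranking, members, p=0)
            expected, _ = walk_oracle(scores, hit_mask, p=0)
            assert es == pytest.approx(expected)

    def test_weighted_matches_oracle(self, rng):
        n = 30
        scores = np.sort(rng.normal(scale=2, size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranking = pd.Series(scores, index=genes)
        members = set(rng.choice(genes, size=8, replace=False))
        es, _ = enrichment_score(ranking, members, p=1)
        expected, path = walk_oracle(scores, [g in members for g in genes], p=1)
        assert es == pytest.approx(expected)
        assert path[-1] == pytest.approx(0.0, abs=1e-12)  # walk returns to zero

    def test_reversal_flips_sign(self, rng):
        n = 50
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranking = pd.Series(scores, index=genes)
        members = set(rng.choice(genes, size=10, replace=False))
        es_fwd, _ = enrichment_score(ranking, members, p=0)
        reversed_ranking = pd.Series(-scores[::-1], index=genes[::-1])
        es_rev, _ = enrichment_score(reversed_ranking, members, p=0)
        assert es_rev == pytest.approx(-es_fwd)

    def test_magnitude_bounded_by_one(self, rng):
        n = 40
        ranking = pd.Series(np.sort(rng.normal(size=n))[::-1],
                            index=[f"g{i}" for i in range(n)])
        for k in (1, 5, 39):
            members = set(ranking.index[:k])
            es, _ = enrichment_score(ranking, members)
            assert abs(es) <= 1.0 + 1e-12

    def test_degenerate_sets_rejected(self):
        ranking = pd.Series([2.0, 1.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(ranking, {"absent"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranking, {"g1", "g2"})


@pytest.fixture(scope="module")
def ranking():
    rng = np.random.default_rng(5)
    scores = np.sort(rng.normal(size=400))[::-1]
    return pd.Series(scores, index=[f"g{i:03d}" for i in range(400)])


class TestPrerankedGsea:

    def test_seeded_determinism(self, ranking, rng):
        sets = {f"s{i}": list(rng.choice(ranking.index, 25, replace=False))
                for i in range(10)}
        r1 = preranked_gsea(ranking, sets, n_perm=200, seed=3)
        r2 = preranked_gsea(ranking, sets, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_random_sets_are_null(self, ranking, rng):
        sets = {f"s{i}": list(rng.choice(ranking.index, 20, replace=False))
                for i in range(200)}
        res = preranked_gsea(ranking, sets, n_perm=500, seed=4)
        frac = (res["pval"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10

    def test_top_concentrated_set_detected(self, ranking):
        sets = {"top": list(ranking.index[:20]),
                **{f"r{i}": list(ranking.index[i::17][:20]) for i in range(10)}}
        res = preranked_gsea(ranking, sets, n_perm=1000, seed=6)
        assert res.loc["top", "padj"] < 0.05
        assert res.loc["top", "ES"] > 0
        assert np.sign(res.loc["top", "NES"]) == np.sign(res.loc["top", "ES"])

    def test_p_resolution_and_monotonicity(self, ranking, rng):
        sets = {f"s{i}": list(rng.choice(ranking.index, 30, replace=False))
                for i in range(40)}
        n_perm = 300
        res = preranked_gsea(ranking, sets, n_perm=n_perm, seed=8)
        assert (res["pval"] >= 1.0 / (n_perm + 1) - 1e-12).all()
        pos = res[res["NES"] > 0].sort_values("NES")
        assert (pos["pval"].diff().dropna() <= 1e-12).all()

    def test_size_bounds_exclude_sets(self, ranking):
        sets = {"small": list(ranking.index[:5]),
                "ok": list(ranking.index[10:40])}
        with pytest.warns(UserWarning, match="size bounds"):
            res = preranked_gsea(ranking, sets, n_perm=100, seed=1,
                                 size_bounds=(15, 500))
        assert res.index.tolist() == ["ok"]

    def test_no_usable_set_warns_and_returns_empty(self, ranking):
        with pytest.warns(UserWarning, match="no gene set"):
            res = preranked_gsea(ranking, {"small": ["g000"]}, n_perm=100, seed=1)
        assert res.empty

    def test_n_perm_floor(self, ranking):
        with pytest.raises(ValueError, match="n_perm"):
            preranked_gsea(ranking, {"s": list(ranking.index[:20])}, n_perm=10)


def test_es_matches_fgsea_reference():
    """Cross-check the walk against the Bioconductor reference implementation."""
    rng = np.random.default_rng(12)
    n = 100
    scores = np.round(np.sort(rng.normal(size=n))[::-1], 6)
    genes = [f"g{i:03d}" for i in range(n)]
    ranking = pd.Series(scores, index=genes)
    sets = {f"s{i}": sorted(rng.choice(genes, size=12, replace=False))
            for i in range(5)}
    ours = {name: enrichment_score(ranking, members, p=1)[0]
            for name, members in sets.items()}
    r_code = f"""
    suppressMessages(library(fgsea)); suppressMessages(library(jsonlite))
    stats <- c({",".join(map(str, scores))})
    names(stats) <- c({",".join(repr(g) for g in genes)})
    sets <- fromJSON('{json.dumps(sets)}')
    es <- sapply(names(sets), function(nm)
        calcGseaStat(stats, selectedStats=which(names(stats) %in% sets[[nm]]),
                     gseaParam=1, scoreType="std"))
    cat(toJSON(as.list(es), auto_unbox=TRUE, digits=NA))
    """
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    reference = json.loads(out.stdout)
    for name in sets:
        assert ours[name] == pytest.approx(reference[name], abs=1e-6)


def test_gmt_roundtrip(tmp_path):
    sets = {"alpha": ["g1", "g2", "g3"], "beta": ["g2", "g9"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
    path.write_text("badline\tonly-two-fields\n")
    with pytest.raises(ValueError, match="GMT"):
        read_gmt(path)


def test_rank_by_score_deterministic_ties():
    scores = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
    ranked = rank_by_score(scores)
    assert ranked.index.tolist() == ["c", "a", "b"]
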
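import numpy as np
import pytest

import triage as tg


@pytest.fixture(scope="session")
def epigenome():
    """Default pseudo-epigenome: 50 planted broad-domain genes of 1000."""
    intervals, genes, truth = tg.simulate_epigenome(seed=1)
    return intervals, genes, truth


@pytest.fixture(scope="session")
def breadth(epigenome):
    intervals, genes, _ = epigenome
    return tg.compute_gene_breadth(intervals, genes)


@pytest.fixture(scope="session")
def rts_table(breadth):
    return tg.compute_rts(breadth)


@pytest.fixture(scope="session")
def big_epigenome():
    """Epigenome with 170 planted genes — enough for knee selection and
    multi-step ablations."""
    intervals, genes, truth = tg.simulate_epigenome(n_regulatory=170, seed=1)
    breadth = tg.compute_gene_breadth(intervals, genes)
    table = tg.compute_rts(breadth)
    priority = tg.select_priority_genes(table)
    return {"intervals": intervals, "genes": genes, "truth": truth,
            "breadth": breadth, "rts": table, "priority": priority}


@pytest.fixture(scope="session")
def atlas(big_epigenome):
    """3-type atlas whose markers are top-RTS priority genes."""
    pri = big_epigenome["priority"]
    markers = {f"type_{t}": pri.genes[3 * t:3 * t + 3] for t in range(3)}
    counts, emb, labels, truth = tg.simulate_atlas(
        marker_map=markers, gene_ids=list(big_epigenome["genes"].index),
        seed=0)
    expr = tg.normalize_library_size(counts)
    return {"counts": counts, "expr": expr, "embedding": emb,
            "labels": labels, "truth": truth, "markers": markers}


@pytest.fixture(scope="session")
def cluster_results(atlas, big_epigenome):
    model = tg.TriageCluster(atlas["expr"], atlas["embedding"],
                             priority=big_epigenome["priority"])
    return model.fit()


@pytest.fixture(scope="session")
def program_breadth():
    breadth, programs = tg.simulate_program_breadth(seed=0)
    gene_list = [g for p in range(3)
                 for g in programs.index[programs == p][:34]][:100]
    return breadth, programs, gene_list


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
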
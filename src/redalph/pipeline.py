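"""Orchestrated end-to-end analysis of an alphabet collection.

From one collection file this derives every downstream artifact: the
all-against-all alphabet similarity matrix, the consensus similarity /
distance matrices (all sources, within-protein sources, chemistry sources),
NJ+OLS dendrograms for each, the leave-one-out jack-knife report, the PCA
of alphabet space, and the row-permutation randomization test between the
two category distance matrices. All randomness flows from a single seed
through named per-stage substreams, so any stage can be re-run in
isolation; outputs are deterministic for a fixed seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alphabet_io import AlphabetCollection, WITHIN_PROTEIN_CATEGORIES, load_collection
from .bigmat import (
    build_consensus,
    build_similarity_matrix,
    similarity_to_distance,
    write_matrix_tsv,
)
from .randstats import RandomizationReport, pca, randomization_test
from .trees import consensus_tree, jackknife_consensus, tree_to_newick


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisBundle:
    """In-memory handles to every artifact of a full run."""

    collection: AlphabetCollection
    similarity: "pd.DataFrame"
    consensus: dict
    trees_newick: dict
    jackknife: "pd.DataFrame"
    pca_variance: np.ndarray
    pca_scores: "pd.DataFrame"
    randtest: RandomizationReport
    metadata: dict


def run_full_analysis(
    collection_path,
    out_dir,
    n_randomizations: int = 100_000,
    seed: int = 0,
) -> AnalysisBundle:
    """Run every stage on *collection_path* and write artifacts to *out_dir*."""
    collection_path = Path(collection_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection = load_collection(collection_path)

    sim = build_similarity_matrix(collection)
    write_matrix_tsv(sim, out / "sim.tsv")

    subsets = {
        "all": collection,
        "protein": collection.by_category(*WITHIN_PROTEIN_CATEGORIES),
        "chem": collection.by_category("chemistry"),
    }
    consensus = {}
    trees_newick = {}
    for tag, sub in subsets.items():
        cons = build_consensus(sub)
        consensus[tag] = cons
        write_matrix_tsv(cons, out / f"consensus_{tag}.tsv")
        nwk = tree_to_newick(consensus_tree(sub))
        trees_newick[tag] = nwk
        (out / f"tree_{tag}.nwk").write_text(nwk)

    jack = jackknife_consensus(collection)
    jack.write_tsv(out / "jackknife.tsv")

    pca_res = pca(sim)
    pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.4f")
    pd.Series(
        pca_res.variance_fractions,
        index=[f"PC{i + 1}" for i in range(len(pca_res.variance_fractions))],
        name="variance_fraction",
    ).to_csv(out / "pca_variance.tsv", sep="\t", float_format="%.6f")

    d_protein = similarity_to_distance(consensus["protein"])
    d_chem = similarity_to_distance(consensus["chem"])
    report, _ = randomization_test(
        d_chem,
        d_protein,
        n=n_randomizations,
        seed=stage_seed(seed, "randtest"),
        mode="rows-of-within-protein",
    )
    report.to_json(out / "randtest.json")

    metadata = {
        "input": str(collection_path),
        "input_sha256": hashlib.sha256(collection_path.read_bytes()).hexdigest(),
        "n_alphabets": len(collection),
        "n_randomizations": n_randomizations,
        "seed": seed,
        "redalph_version": __version__,
    }
    (out / "run.json").write_text(json.dumps(metadata, indent=2) + "\n")

    return AnalysisBundle(
        collection=collection,
        similarity=sim.to_frame(),
        consensus=consensus,
        trees_newick=trees_newick,
        jackknife=jack.to_frame(),
        pca_variance=pca_res.variance_fractions,
        pca_scores=pca_res.scores,
        randtest=report,
        metadata=metadata,
    )
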
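"""Self-contained benchmark pipelines on synthetic data with known truth.

Each function generates its own inputs from a seed, runs the regular
pipeline entry points, and returns the measured quantities: statistical
calibration and planted-marker recovery for the differential test, the
structural interface arm end to end, and the network arm against direct
linear-algebra references.  These are the package's own quality gates; the
test suite asserts on them and the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from flipms import io, simulate
from flipms.diffstats import PeptideAnova, median_normalize
from flipms.markers import build_library
from flipms.network import personalized_pagerank, propagate_and_cluster, walktrap_clusters
from flipms.simulate import (
    FRACTIONS,
    PlantedMarker,
    SimulationTruth,
    TOY_REFERENCE,
    simulate_dimer_structure,
    simulate_complex_network,
)
from flipms.structure import detect_interface, interface_roc, peptide_distance_table


def _prepare(lip, ctrl):
    records = pd.concat([lip, ctrl], ignore_index=True)
    records = io.detection_filter(records)
    records = median_normalize(records, scope="per_group")
    return (
        records[records["sample_type"] == "lip"],
        records[records["sample_type"] == "tryptic_control"],
    )


def null_calibration(seed: int, n_peptides: int = 2000) -> dict:
    """Raw-p calibration of the differential ANOVA on a no-marker simulation.

    Study conditions: 4 fractions x 4 replicates, 10% CV log-normal noise,
    ``n_peptides`` peptides, no planted markers.  Returns the fraction of raw
    p below 0.05 for both mean-square variants.
    """
    proteome = simulate.make_proteome(160, (80, 300), seed=seed)
    ann = simulate.digest_in_silico(proteome, seed=seed + 1).head(n_peptides)
    truth = simulate.default_truth(proteome, ann, n_markers=0, seed=seed + 2)
    lip, ctrl = simulate.simulate_flip_experiment(truth, proteome, ann)
    lip, ctrl = _prepare(lip, ctrl)
    out = {"n_peptides": 0}
    for variant in ("textbook", "as_printed"):
        res = PeptideAnova(
            lip, ctrl, variant=variant, renormalize_ratios=True
        ).fit(pairwise=False)
        p = res.table["p"].dropna()
        out[f"frac_p_lt_05_{variant}"] = float((p < 0.05).mean())
        out["n_peptides"] = int(len(p))
    return out


def marker_recovery(
    seed: int, n_markers: int = 50, log2fc: float = 1.0, n_proteins: int = 120
) -> dict:
    """Planted-marker recovery under the study conditions (10% CV, 4 x 4).

    Builds the marker library with the calibrated (textbook) statistics and
    scores it against the planted regions: recall and precision at q < 0.05
    and the peptide-level ROC AUC of ranking by q.
    """
    proteome = simulate.make_proteome(n_proteins, (80, 300), seed=seed)
    ann = simulate.digest_in_silico(proteome, seed=seed + 1)
    truth = simulate.default_truth(
        proteome, ann, n_markers=n_markers, log2fc=log2fc, seed=seed + 2
    )
    lip, ctrl = simulate.simulate_flip_experiment(truth, proteome, ann)
    lip, ctrl = _prepare(lip, ctrl)
    res = PeptideAnova(
        lip, ctrl, variant="textbook", renormalize_ratios=True, annotations=ann
    ).fit()
    mw = {acc: simulate.protein_mw_kda(s) for acc, s in proteome.items()}
    library, _ = build_library(res.regions, res.pairwise, mw)

    planted = truth.marker_regions()
    got = set(map(tuple, library[["protein_id", "start", "end"]].values))
    tp = len(got & planted)
    recall = tp / len(planted)
    precision = tp / len(got) if got else float("nan")

    marker_peps = truth.marker_peptides(ann)
    table = res.table.dropna(subset=["q"])
    labels = table.index.isin(marker_peps)
    scores = -np.log10(table["q"].to_numpy() + 1e-300)
    auc = interface_roc(labels, scores)["auc"]
    return {
        "n_planted": len(planted),
        "n_library": len(got),
        "recall": recall,
        "precision": precision,
        "q_ranking_auc": float(auc),
    }


def _tryptic_block_sequence(rng, n_blocks: int = 8, block: int = 8) -> str:
    """Chain sequence as a tiling of length-8 fully tryptic peptides, so the
    interface patch is always covered by digest products of legal length."""
    non_kr = [a for a in simulate.AMINO_ACIDS if a not in "KR"]
    out = []
    for _ in range(n_blocks):
        out.append("".join(rng.choice(non_kr, size=block - 1)) + rng.choice(["K", "R"]))
    return "".join(out)


def interface_benchmark(seed: int, cutoff: float = 2.6) -> dict:
    """End-to-end structural arm on a synthetic heterodimer.

    Two 64-residue chains tiled by tryptic peptides form a dimer with a
    12-residue central contact patch; markers are planted exactly on the
    patch regions, the differential pipeline is run, peptides are mapped
    back onto the structure and the significance score is evaluated as a
    predictor of interface proximity.
    """
    rng = np.random.default_rng(seed)
    seq_a, seq_b = _tryptic_block_sequence(rng), _tryptic_block_sequence(rng)
    width = 12
    structure, planted_residues = simulate_dimer_structure(
        sequences=(seq_a, seq_b), interface_width=width, seed=seed
    )
    iface = detect_interface(structure, reference=TOY_REFERENCE)
    detected = set(
        map(tuple, iface[iface["is_interface"]][["chain_id", "residue_index"]].values)
    )
    tp = len(detected & planted_residues)
    sensitivity = tp / len(planted_residues)
    precision = tp / len(detected) if detected else float("nan")

    proteome = {"PA": seq_a, "PB": seq_b}
    ann = simulate.digest_in_silico(proteome, pk_sites_per_protein=2, seed=seed + 1)
    start0 = (64 - width) // 2  # 0-based patch start
    patch = (start0 + 1, start0 + width)  # 1-based inclusive
    abundance = {
        acc: {f: float(10 ** (6 + rng.normal(0, 0.2))) for f in FRACTIONS}
        for acc in proteome
    }
    truth = SimulationTruth(
        seed=seed + 2,
        fraction_abundance=abundance,
        planted_markers=[
            PlantedMarker("PA", *patch, 1.0),
            PlantedMarker("PB", *patch, 1.0),
        ],
    )
    lip, ctrl = simulate.simulate_flip_experiment(truth, proteome, ann)
    lip, ctrl = _prepare(lip, ctrl)
    res = PeptideAnova(lip, ctrl, variant="textbook", renormalize_ratios=True).fit(
        pairwise=False
    )

    table = res.table.dropna(subset=["q"])
    dist = peptide_distance_table(
        structure, list(table.index), interface=iface, cutoffs=(cutoff,),
        seed=seed + 3,
    ).set_index("peptide_id")
    merged = table.join(dist, how="inner")
    labels = merged[f"interface_lt_{cutoff:g}"].to_numpy()
    scores = -np.log10(merged["q"].to_numpy() + 1e-300)
    markers = merged["q"].to_numpy() < 0.05
    roc = interface_roc(labels, scores, markers=markers)

    # exhaustive distance oracle: plain loops over residues and interface CAs
    iface_ca = [
        structure.chain(c).ca[i]
        for c, i in iface[iface["is_interface"]][
            ["chain_id", "residue_index"]
        ].itertuples(index=False, name=None)
    ]
    max_rel_err = 0.0
    for pep, row in dist.iterrows():
        chain = structure.chain(row["chain_id"])
        per_res = [
            min(float(np.linalg.norm(chain.ca[i] - c)) for c in iface_ca)
            for i in range(int(row["start"]), int(row["end"]) + 1)
        ]
        expected = sum(per_res) / len(per_res)
        if expected > 0:
            max_rel_err = max(max_rel_err, abs(row["distance"] - expected) / expected)
        else:
            max_rel_err = max(max_rel_err, abs(row["distance"] - expected))
    return {
        "interface_sensitivity": sensitivity,
        "interface_precision": precision,
        "n_mapped_peptides": int(len(merged)),
        "roc_auc": float(roc["auc"]),
        "distance_max_abs_err_vs_oracle": float(max_rel_err),
    }


def network_benchmark(seed: int) -> dict:
    """Network arm: propagation against a direct linear solve, walktrap
    recovery of planted cliques, and pipeline determinism."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    graph = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**16)))
    seeds = [0, 3]
    scores = personalized_pagerank(graph, seeds)

    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    r = np.zeros(n)
    for s in seeds:
        r[idx[s]] = 1.0 / len(seeds)
    M = np.zeros((n, n))
    for u in nodes:
        nbrs = list(graph.neighbors(u))
        if nbrs:
            for v in nbrs:
                M[idx[u], idx[v]] = 1.0 / len(nbrs)
        else:
            M[idx[u], :] = r
    x = np.linalg.solve(np.eye(n) - 0.9 * M.T, 0.1 * r)
    x = x / x.sum()
    pagerank_err = max(abs(scores[node] - x[idx[node]]) for node in nodes)

    clique_recovery = {}
    for k in (2, 3, 4):
        g, _, partition = simulate_complex_network([5] * k, 0, seed=seed + k)
        communities = walktrap_clusters(g)
        clique_recovery[k] = int(
            sorted(map(sorted, communities)) == sorted(map(sorted, partition))
        )

    g, complexes, _ = simulate_complex_network([5, 6, 4], 4, seed=seed + 10)
    seed_nodes = sorted(g.nodes)[:4]
    a = propagate_and_cluster(g, seed_nodes, complexes)
    b = propagate_and_cluster(g, seed_nodes, complexes)
    deterministic = int(a.equals(b))
    return {
        "pagerank_max_abs_err_vs_solve": float(pagerank_err),
        "walktrap_k2_exact": clique_recovery[2],
        "walktrap_k3_exact": clique_recovery[3],
        "walktrap_k4_exact": clique_recovery[4],
        "network_stage_deterministic": deterministic,
    }
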
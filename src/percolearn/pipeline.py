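"""End-to-end orchestration: generate -> percolate -> onion -> scan -> confusion.

A single master seed spawns one labeled sub-stream per stage, so a config
reproduces bit-identical artifacts without coupling the stages.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import confusion as conf
from . import netgen, onion, percolation, phase_clustering as pc
from .config import RunConfig

log = logging.getLogger("percolearn")

_STAGES = ("network", "percolation", "scan", "confusion")


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


def build_network(cfg: RunConfig):
    net = cfg.network
    if net.kind == "lattice":
        return netgen.make_square_lattice(net.size)
    if net.kind == "powerlaw":
        s = _stage_seed(cfg.seed, "network")
        deg = netgen.sample_powerlaw_degrees(net.size, net.gamma, net.kmin, seed=s)
        return netgen.configuration_model_graph(deg, seed=s + 1)
    if net.kind == "edgelist":
        if not net.path:
            raise ValueError("network.path required for kind=edgelist")
        return netgen.read_edge_list(net.path)
    raise ValueError(f"unknown network.kind {net.kind!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, writing every intermediate artifact to outdir.

    Returns the JSON-serializable report (also written to report.json).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    def timed(stage):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            log.info("stage=%s seed=%s wall=%.2fs", stage, cfg.seed, dt)
            report["stages"][stage] = round(dt, 3)

        return done

    d = timed("network")
    g = build_network(cfg)
    netgen.write_edge_list(g, outdir / "graph.edgelist")
    d()

    d = timed("percolation")
    pseed = _stage_seed(cfg.seed, "percolation")
    phic = percolation.estimate_phic_ground_truth(
        g, dphi=cfg.percolation.dphi, n_runs=cfg.percolation.runs,
        seed=pseed, mode=cfg.percolation.mode,
    )
    X = percolation.build_state_matrix(
        g, dphi=cfg.percolation.dphi, seed=pseed, mode=cfg.percolation.mode
    )
    # labels pair X with its own realization's transition; the averaged
    # estimate above is the ensemble-level reference
    y = percolation.make_labels(X.phis, X.realization_phic)
    X.to_csv(outdir / "X.csv")
    y.to_csv(outdir / "y.csv", phis=X.phis)
    (outdir / "phic.txt").write_text(f"{phic}\n")
    d()

    d = timed("scan")
    od = onion.onion_decomposition(g)
    od.to_csv(outdir / "onion.csv")
    onion.onion_spectrum(od).to_csv(outdir / "onion_spectrum.csv")
    sseed = _stage_seed(cfg.seed, "scan")
    if cfg.sampling.mode == "random":
        bins = pc.random_bins(
            sorted(g.nodes()), cfg.sampling.bin_size, cfg.sampling.n_random_bins, seed=sseed
        )
    else:
        ordered = onion.order_nodes_core_to_periphery(od)
        bins = pc.bin_nodes(ordered, cfg.sampling.bin_size)
    accs = pc.layer_accuracy_scan(
        X, y, bins, seed=sseed,
        sigma2=cfg.clustering.sigma2, perplexity=cfg.clustering.perplexity,
    )
    with open(outdir / "scan.csv", "w") as fh:
        fh.write("bin_index,provenance,accuracy\n")
        for b, a in zip(bins, accs):
            fh.write(f"{b.bin_index},{b.provenance},{a}\n")
    # confusion input: the most coherent of the top-accuracy bins
    best_bin, best_acc, _ = pc.refine_by_coherence(X, bins, accs)
    d()

    d = timed("confusion")
    ccfg = conf.ClassifierConfig(
        hidden_units=cfg.confusion.hidden_units,
        dropout_p=cfg.confusion.dropout_p,
        learning_rate=cfg.confusion.learning_rate,
        epochs=cfg.confusion.epochs,
        batch_size=cfg.confusion.batch_size,
        test_fraction=cfg.confusion.test_fraction,
    )
    cseed = _stage_seed(cfg.seed, "confusion")
    # the classifier sees the same noise-spread matrix the clustering stage saw
    Xsub = pc.add_noise(
        X.columns(best_bin.nodes), sigma2=cfg.clustering.sigma2, seed=cseed
    )
    curve = conf.confusion_sweep(
        Xsub, X.phis, delta=cfg.confusion.delta, cfg=ccfg, seed=cseed,
    )
    curve.to_csv(outdir / "curve.csv")
    d()

    report.update(
        {
            "phic_ground_truth": phic,
            "phic_realization": X.realization_phic,
            "phic_hat": curve.phic_hat,
            "low_confidence": curve.low_confidence,
            "best_bin": {
                "index": best_bin.bin_index,
                "provenance": best_bin.provenance,
                "accuracy": best_acc,
            },
            "scan_mean_accuracy": float(np.mean(accs)),
            "manifest": sorted(
                p.name for p in outdir.iterdir() if p.name != "report.json"
            ),
        }
    )
    del report["stages"]  # wall times are not deterministic; keep report bit-stable
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
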
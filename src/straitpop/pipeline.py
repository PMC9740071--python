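"""End-to-end orchestration: simulate or load data, then run diversity,
neutrality, AMOVA/PhiST, networks, divergence and (optionally) landscape
and morphology stages into one report directory with a run manifest.

One global seed is expanded into independent per-stage substreams keyed by
stage name, so adding a stage never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, differentiation, diversity, network
from .alignment import (AnalysisConfig, read_fasta_alignment,
                        read_population_map, subset_alignment,
                        write_fasta_alignment)
from .simulate import DEMES, IMModel, LocusSpec, simulate_dataset

log = logging.getLogger("straitpop")

__all__ = ["stage_rng", "run_pipeline", "setup_logging"]


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named stage under one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def default_loci() -> list[LocusSpec]:
    """The study's marker panel shape: three nuclear introns (~400 bp) and
    one effectively smaller concatenated chloroplast locus."""
    return [
        LocusSpec("AGT_intron1", 400),
        LocusSpec("GroES_intron1", 400),
        LocusSpec("LFY_intron1", 393),
        LocusSpec("cpDNA", 800, inheritance_scale=0.25),
    ]


def run_pipeline(outdir, config: AnalysisConfig | None = None,
                 alignments: dict[str, Path] | None = None,
                 population_map: Path | None = None,
                 simulate: bool = False,
                 samples_per_deme: int = 10,
                 populations_per_deme: int = 2) -> Path:
    """Run every applicable stage; returns the report directory.

    Either pass real inputs (``alignments`` mapping locus name to FASTA
    path plus ``population_map``) or set ``simulate=True`` to generate a
    dataset under the default isolation-with-migration history.
    """
    cfg = config or AnalysisConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": f"straitpop {__version__}",
        "started": datetime.now(timezone.utc).isoformat(),
        "config": asdict(cfg),
        "seed": cfg.rng_seed,
        "inputs": {},
        "outputs": {},
    }

    if simulate:
        log.info("simulating dataset under the default IM history")
        model = IMModel.conandron(mu=cfg.mutation_rate_per_site_per_year)
        loci = default_loci()
        alns, pmap = simulate_dataset(
            model, loci, {d: samples_per_deme for d in DEMES},
            seed=stage_rng(cfg.rng_seed, "simulate"),
            populations_per_deme=populations_per_deme,
        )
        simdir = out / "simulated"
        simdir.mkdir(exist_ok=True)
        for aln in alns:
            write_fasta_alignment(aln, simdir / f"{aln.locus_name}.fasta")
        pmap.to_tsv(simdir / "population_map.tsv")
        truth = {
            "ne": {"HS": model.ne_hs, "C": model.ne_c, "TI": model.ne_ti},
            "t0_years": model.t0, "t1_years": model.t1, "mu": model.mu,
        }
        (simdir / "true_parameters.json").write_text(json.dumps(truth, indent=2))
        manifest["inputs"]["simulated"] = {
            f.name: _hash_file(f) for f in sorted(simdir.iterdir())
        }
    else:
        if not alignments or population_map is None:
            raise ValueError("need alignments and a population map (or simulate=True)")
        alns = [read_fasta_alignment(p, name) for name, p in alignments.items()]
        pmap = read_population_map(population_map)
        for w in pmap.warnings:
            log.warning("population map: %s", w)
        manifest["inputs"] = {name: _hash_file(Path(p))
                              for name, p in alignments.items()}
        manifest["inputs"]["population_map"] = _hash_file(Path(population_map))

    # diversity + neutrality, per locus x unit
    rows = []
    rng_neu = stage_rng(cfg.rng_seed, "neutrality")
    for aln in alns:
        units = ["species"] + pmap.groups() + pmap.populations()
        for unit in units:
            sub = aln if unit == "species" else subset_alignment(aln, pmap, unit)
            if sub.n < 2:
                continue
            st = diversity.summarize(sub, unit=f"{aln.locus_name}:{unit}",
                                     reps=cfg.coalescent_reps, seed=rng_neu)
            rows.append(asdict(st))
    div_path = out / "diversity.tsv"
    pd.DataFrame(rows).to_csv(div_path, sep="\t", index=False)
    log.info("diversity table -> %s", div_path)

    # AMOVA and pairwise PhiST per locus (needs >= 2 groups)
    amova_rows, fst_blocks = [], []
    rng_amova = stage_rng(cfg.rng_seed, "amova")
    for aln in alns:
        try:
            res = differentiation.amova(aln, pmap,
                                        permutations=cfg.permutations,
                                        seed=rng_amova)
        except ValueError as e:
            log.warning("AMOVA skipped for %s: %s", aln.locus_name, e)
            continue
        for level, i in (("Among groups", 0),
                         ("Among populations within groups", 1),
                         ("Within populations", 2)):
            amova_rows.append({
                "locus": aln.locus_name, "source": level, "df": res.df[i],
                "SS": round(res.ss[i], 3), "variance": round(res.sigma2[i], 4),
                "percent": round(res.percent[i], 2),
            })
        amova_rows.append({
            "locus": aln.locus_name, "source": "Fixation indices",
            "df": "", "SS": "",
            "variance": (f"PhiCT={res.phi_ct:.3f} PhiSC={res.phi_sc:.3f} "
                         f"PhiST={res.phi_st:.3f}"),
            "percent": f"p={res.p_ct:.4g}/{res.p_sc:.4g}/{res.p_st:.4g}",
        })
        units, phi, pv = differentiation.pairwise_phist(
            aln, pmap, permutations=cfg.permutations, seed=rng_amova)
        block = pd.DataFrame(phi, index=units, columns=units).round(3)
        stars = np.where(pv < 0.001, "***",
                         np.where(pv < 0.01, "**", np.where(pv < 0.05, "*", "")))
        fst_blocks.append((aln.locus_name, block,
                           pd.DataFrame(stars, index=units, columns=units)))
    pd.DataFrame(amova_rows).to_csv(out / "amova.tsv", sep="\t", index=False)
    with open(out / "pairwise_phist.tsv", "w") as fh:
        for name, block, stars in fst_blocks:
            fh.write(f"# {name}\n")
            block.to_csv(fh, sep="\t")
            stars.to_csv(fh, sep="\t")
            fh.write("\n")

    # haplotype networks
    import networkx as nx
    fixed = cfg.fixed_connection_limit
    for aln in alns:
        coding = network.encode_indels(aln)
        nodes = network.collapse_haplotypes(coding)
        dmat = network.haplotype_distances(nodes)
        limit = network.connection_limit(coding.nucleotides.length, fixed=fixed)
        net = network.build_network(nodes, dmat, limit)
        for hid, counts in zip(nodes.ids, nodes.population_counts(pmap)):
            net.graph.nodes[hid]["populations"] = json.dumps(counts)
        nx.write_graphml(net.graph, out / f"network_{aln.locus_name}.graphml")
        steps = network.group_step_distance(dmat, nodes, pmap)
        with open(out / f"network_{aln.locus_name}_steps.tsv", "w") as fh:
            fh.write("group_a\tgroup_b\tmin_steps\tmax_steps\n")
            for (a, b), (lo, hi) in steps.items():
                fh.write(f"{a}\t{b}\t{lo}\t{hi}\n")

    # divergence summary on the concatenated nuclear loci
    nuclear = [a for a in alns if a.locus_name != "cpDNA"]
    target = nuclear if nuclear else alns
    summaries = differentiation.multilocus_divergence(
        target, pmap, cfg.mutation_rate_per_site_per_year)
    with open(out / "divergence.tsv", "w") as fh:
        fh.write("pair\tdxy\tda\tt_hat_years\tnote\n")
        for s in summaries:
            fh.write(f"{s.pair[0]}-{s.pair[1]}\t{s.dxy:.6g}\t{s.da:.6g}\t"
                     f"{s.t_hat_years:.6g}\t{s.note}\n")

    manifest["outputs"] = {
        f.name: _hash_file(f) for f in sorted(out.iterdir()) if f.is_file()
    }
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("report complete -> %s", out)
    return out
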
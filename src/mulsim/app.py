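"""Command-line front end wiring the pipeline end to end.

Subcommands: ``similarity`` (two edge-list files -> similarity TSV),
``align`` (similarity TSV -> node mapping), ``generate`` (synthetic
benchmark suite -> edge-list + truth files), ``evaluate`` (suite dir ->
NC-vs-noise table and pooled KPIs).  Exit codes: 1 for parse failures,
2 for the equal-layer-count violation.  The single configured seed fans
out to stage-specific derived seeds so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np

from . import __version__, alignval, benchgen, netio
from .estimators import PairwiseNodeSimilarity
from .netio import NodeRef
from .simscore import LayerBlock, SimilarityMatrix

logger = logging.getLogger("mulsim")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed: stable hash of (seed, stage), below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_config(path: Path) -> dict:
    """Read a config file: JSON object, or line-oriented ``key=value``."""
    text = path.read_text()
    try:
        obj = json.loads(text)
        if not isinstance(obj, dict):
            raise ValueError("config JSON must be an object")
        return obj
    except json.JSONDecodeError:
        pass
    config: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        config[key.strip().replace("-", "_")] = value.strip()
    return config


class ConfigCommand(click.Command):
    """Command whose ``--config FILE`` supplies defaults; flags override."""

    def invoke(self, ctx):
        path = ctx.params.pop("config", None)
        if path is not None:
            for key, value in load_config(Path(path)).items():
                if key in ctx.params and ctx.get_parameter_source(
                    key
                ) == click.core.ParameterSource.DEFAULT:
                    param = next(p for p in self.params if p.name == key)
                    ctx.params[key] = param.type.convert(value, param, ctx)
        return super().invoke(ctx)


def config_option(fn):
    return click.option(
        "--config", type=click.Path(exists=True, path_type=Path),
        default=None, help="config file (JSON or key=value); flags override",
    )(fn)


def _setup_logging(log_level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, log_level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
@click.version_option(__version__)
def cli(log_level: str) -> None:
    """Cross-network node similarity for multilayer networks."""
    _setup_logging(log_level)


@cli.command(cls=ConfigCommand)
@config_option
@click.option("--source", required=True, type=click.Path(exists=True, path_type=Path))
@click.option("--target", required=True, type=click.Path(exists=True, path_type=Path))
@click.option("--out", required=True, type=click.Path(path_type=Path))
@click.option("--input-channels", default=64, show_default=True)
@click.option("--hidden-channels", default=None, type=int)
@click.option("--output-channels", default=None, type=int)
@click.option("--seed", default=0, show_default=True)
def similarity(source, target, out, input_channels, hidden_channels,
               output_channels, seed) -> None:
    """Score same-layer node pairs of two multilayer networks."""
    try:
        with open(source) as fh:
            net_s = netio.read_edge_list(fh)
        with open(target) as fh:
            net_t = netio.read_edge_list(fh)
    except (netio.MalformedEdgeError, netio.NetworkValidationError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    if net_s.n_layers != net_t.n_layers:
        click.echo(
            "error: the two multilayer networks must have the same number "
            f"of layers ({net_s.n_layers} vs {net_t.n_layers})",
            err=True,
        )
        sys.exit(2)
    model_seed = derive_seed(seed, "gin-init")
    logger.info("embedding with GIN seed %d", model_seed)
    est = PairwiseNodeSimilarity(
        input_channels=input_channels,
        hidden_channels=hidden_channels,
        output_channels=output_channels,
        random_state=model_seed,
    ).fit((net_s, net_t))
    out.mkdir(parents=True, exist_ok=True)
    sim_path = out / "similarity.tsv"
    with open(sim_path, "w") as fh:
        rows = netio.write_similarity(est.similarity_, fh)
    manifest = {
        "version": __version__,
        "seed": seed,
        "gin_seed": model_seed,
        "input_channels": input_channels,
        "layer_sizes_source": {
            lay: len(net_s.layer_nodes(lay)) for lay in net_s.layer_order
        },
        "layer_sizes_target": {
            lay: len(net_t.layer_nodes(lay)) for lay in net_t.layer_order
        },
        "rows_written": rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    click.echo(f"wrote {rows} similarity rows to {sim_path}")


def _matrix_from_tsv(path: Path) -> SimilarityMatrix:
    with open(path) as fh:
        rows = netio.read_similarity(fh)
    by_layer: dict[str, dict[tuple[str, str], float]] = {}
    for s, t, lay, val in rows:
        by_layer.setdefault(lay, {})[(s, t)] = val
    blocks = []
    for lay, entries in by_layer.items():
        sources = sorted({s for s, _ in entries})
        targets = sorted({t for _, t in entries})
        values = np.zeros((len(sources), len(targets)))
        for (s, t), val in entries.items():
            values[sources.index(s), targets.index(t)] = val
        blocks.append(
            LayerBlock(
                layer=lay,
                source_order=[NodeRef(s, lay) for s in sources],
                target_order=[NodeRef(t, lay) for t in targets],
                values=values,
            )
        )
    return SimilarityMatrix(blocks=blocks)


@cli.command(name="align")
@click.option("--matrix", "matrix_path", required=True,
              type=click.Path(exists=True, path_type=Path))
@click.option("--method", type=click.Choice(["matching", "greedy"]),
              default="matching", show_default=True)
@click.option("--out", default="-", type=click.Path(path_type=Path, allow_dash=True))
def align_cmd(matrix_path, method, out) -> None:
    """Build a node mapping from a similarity TSV."""
    matrix = _matrix_from_tsv(matrix_path)
    mapping = alignval.align(matrix, method=method)
    if str(out) == "-":
        alignval.write_mapping(mapping, sys.stdout)
    else:
        with open(out, "w") as fh:
            n = alignval.write_mapping(mapping, fh)
        click.echo(f"wrote {n} mapped pairs to {out}")


@cli.command(cls=ConfigCommand)
@config_option
@click.option("--n-layers", default=2, show_default=True)
@click.option("--nodes", default=50, show_default=True)
@click.option("--m", default=2, show_default=True)
@click.option("--p", default=0.5, show_default=True)
@click.option("--q", default=0.4, show_default=True)
@click.option("--z", default=10.0, show_default=True)
@click.option("--noise", default="5,10,15,20,25", show_default=True,
              help="comma-separated noise percentages")
@click.option("--num-base", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path(path_type=Path))
def generate(n_layers, nodes, m, p, q, z, noise, num_base, seed, out) -> None:
    """Generate a synthetic benchmark suite with ground-truth mappings."""
    levels = tuple(float(x) / 100.0 for x in noise.split(","))
    params = benchgen.GenParams(n_layers=n_layers, n=nodes, m=m, p=p, q=q, z=z)
    suite = benchgen.build_suite(
        num_base=num_base, noise_levels=levels, params=params,
        seed=derive_seed(seed, "benchgen"),
    )
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "params": params.__dict__, "samples": []}
    written_bases: set[int] = set()
    for i, sample in enumerate(suite):
        base_name = f"base{sample.base_id:02d}.tsv"
        if sample.base_id not in written_bases:
            with open(out / base_name, "w") as fh:
                netio.write_edge_list(sample.source, fh)
            written_bases.add(sample.base_id)
        pct = round(sample.noise_level * 100)
        noisy_name = f"base{sample.base_id:02d}_noise{pct:02d}.tsv"
        with open(out / noisy_name, "w") as fh:
            netio.write_edge_list(sample.target, fh)
        truth_name = f"base{sample.base_id:02d}_noise{pct:02d}.truth.tsv"
        with open(out / truth_name, "w") as fh:
            alignval.write_mapping(sample.truth, fh)
        manifest["samples"].append(
            {"source": base_name, "target": noisy_name, "truth": truth_name,
             "noise_level": sample.noise_level}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    click.echo(f"wrote {len(suite)} samples to {out}")


def _read_truth(path: Path) -> alignval.NodeMapping:
    pairs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("source\t"):
                continue
            s, t, lay = line.split("\t")
            pairs[NodeRef(s, lay)] = NodeRef(t, lay)
    return alignval.NodeMapping(pairs=pairs)


@cli.command()
@click.option("--suite", required=True, type=click.Path(exists=True, path_type=Path))
@click.option("--out", required=True, type=click.Path(path_type=Path))
@click.option("--seed", default=0, show_default=True)
@click.option("--threshold", default=0.95, show_default=True)
def evaluate(suite, out, seed, threshold) -> None:
    """Run the full evaluation over a generated suite: NC table + KPIs."""
    manifest = json.loads((suite / "manifest.json").read_text())
    model_seed = derive_seed(seed, "gin-init")
    nc_by_level: dict[float, list[float]] = {}
    all_labels, all_preds, all_scores = [], [], []
    for entry in manifest["samples"]:
        with open(suite / entry["source"]) as fh:
            src = netio.read_edge_list(fh)
        with open(suite / entry["target"]) as fh:
            tgt = netio.read_edge_list(fh)
        truth = _read_truth(suite / entry["truth"])
        est = PairwiseNodeSimilarity(random_state=model_seed).fit((src, tgt))
        nc = alignval.node_correctness(est.predict(), truth)
        nc_by_level.setdefault(entry["noise_level"], []).append(nc)
        labels, preds, scores = alignval.classify(
            est.similarity_, truth, threshold=threshold
        )
        all_labels.append(labels)
        all_preds.append(preds)
        all_scores.append(scores)
    report = alignval.kpis(
        np.concatenate(all_labels), np.concatenate(all_preds),
        np.concatenate(all_scores),
    )
    nc_table = [
        {
            "noise_percent": round(level * 100),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
        for level, vals in sorted(nc_by_level.items())
    ]
    out.mkdir(parents=True, exist_ok=True)
    (out / "kpis.json").write_text(json.dumps(report.as_dict(), indent=2))
    with open(out / "nc_by_noise.tsv", "w") as fh:
        fh.write("noise_percent\tmean\tsd\tmin\tmax\n")
        for row in nc_table:
            fh.write(
                f"{row['noise_percent']}\t{row['mean']:.6f}\t{row['sd']:.6f}"
                f"\t{row['min']:.6f}\t{row['max']:.6f}\n"
            )
    click.echo(json.dumps({"kpis": report.as_dict(), "nc": nc_table}, indent=2))


def main() -> None:
    cli()


if __name__ == "__main__":
    main()
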
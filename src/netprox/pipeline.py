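"""End-to-end screen orchestration: load → filter → merge → rank → report.

``run_screen`` executes the whole prioritization on the files named in a
:class:`~netprox.config.RunConfig` and leaves a ranked proximity table plus a
run manifest (seeds, parameters, input checksums, dropped counts, package
version) in the output directory. Inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .cti import (
    CompoundFilter,
    filter_compounds_by_qed,
    filter_predictions_by_score,
    merge_validated_predicted,
    read_cti_table,
)
from .errors import ValidationError
from .interactome import largest_connected_component, load_edge_list, load_node_mapping
from .proximity import (
    DiseaseProteinSet,
    PROCESS_GROUPS,
    results_to_frame,
    screen_compounds,
)

logger = logging.getLogger(__name__)

__all__ = ["read_disease_proteins", "read_qed_table", "run_screen"]


def read_disease_proteins(path: str | Path, delimiter: str = "\t") -> DiseaseProteinSet:
    """Read a disease-protein list: one id per line, optional group column.

    With a header line ``protein_id[<tab>process_group]`` the second column
    must use the standard process-group vocabulary.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read disease set {path}: {exc}") from exc
    proteins: set[str] = set()
    groups: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(delimiter) if f.strip()]
        if lineno == 1 and fields[0].lower() in ("protein_id", "protein", "id"):
            continue
        proteins.add(fields[0])
        if len(fields) > 1:
            if fields[1] not in PROCESS_GROUPS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown process group {fields[1]!r}"
                )
            groups[fields[0]] = fields[1]
    if not proteins:
        raise ValidationError(f"disease set {path} is empty")
    return DiseaseProteinSet(proteins=proteins, process_group=groups)


def read_qed_table(path: str | Path, delimiter: str = "\t") -> dict[str, float]:
    """Read per-compound QED scores (columns: compound_id, qed)."""
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except OSError as exc:
        raise ValidationError(f"cannot read QED table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValidationError(f"QED table {path} needs two columns")
    cols = df.columns[:2]
    return {
        str(c).strip(): float(q) for c, q in df[cols].itertuples(index=False)
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_screen(config: RunConfig) -> pd.DataFrame:
    """Execute the full proximity screen described by ``config``.

    Stages: load interactome (largest component) → optional QED filter →
    prediction-score filter → validated/predicted merge → degree-matched
    proximity screen. Writes ``ranked_proximity.tsv`` and ``manifest.yaml``
    under the configured output directory and returns the ranked table.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    mapping = load_node_mapping(config.node_mapping) if config.node_mapping else None
    g_full = load_edge_list(config.interactome, mapping=mapping)
    g = largest_connected_component(g_full)

    cti = read_cti_table(config.cti)
    n_raw = len(cti)
    if config.qed is not None:
        qed = read_qed_table(config.qed)
        keep = filter_compounds_by_qed(
            set(cti["compound_id"]),
            CompoundFilter(qed_scores=qed, qed_threshold=config.qed_threshold),
        )
        cti = cti[cti["compound_id"].isin(keep)].reset_index(drop=True)
    validated = cti[cti["source"] == "validated"].reset_index(drop=True)
    predicted = cti[cti["source"] == "predicted"].reset_index(drop=True)
    predicted = filter_predictions_by_score(predicted, config.score_threshold)
    cti = merge_validated_predicted(validated, predicted)
    if len(cti) == 0:
        raise ValidationError("no CTI rows survive the filters")

    disease = read_disease_proteins(config.disease)
    results = screen_compounds(
        cti,
        disease,
        g,
        n_iterations=config.n_iterations,
        min_bin_size=config.min_bin_size,
        seed=config.seed,
    )
    table = results_to_frame(results)
    table_path = outdir / "ranked_proximity.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")

    manifest = {
        "netprox_version": __version__,
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "min_bin_size": config.min_bin_size,
        "qed_threshold": config.qed_threshold,
        "score_threshold": config.score_threshold,
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("interactome", "cti", "disease", "qed", "annotations")
            if getattr(config, name) is not None
        },
        "interactome_nodes_total": g_full.number_of_nodes(),
        "interactome_nodes_lcc": g.number_of_nodes(),
        "interactome_edges_lcc": g.number_of_edges(),
        "nodes_dropped_outside_lcc": g_full.number_of_nodes() - g.number_of_nodes(),
        "cti_rows_input": n_raw,
        "cti_rows_used": len(cti),
        "disease_proteins": len(disease.proteins),
        "disease_proteins_in_lcc": len(disease.proteins & set(g.nodes)),
        "compounds_ranked": len(table),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    logger.info("screen complete: %d compounds ranked -> %s", len(table), table_path)
    return table
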
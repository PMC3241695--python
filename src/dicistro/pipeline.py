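"""End-to-end orchestration: characterize a genome, fit/apply the NCA model.

Both entry points write machine-readable TSV/GFF3/JSON artifacts into an
output directory and return the same numbers as a dict, so every report
figure is recomputable from the intermediates.  On a stage failure the
partially written outputs are removed and a :class:`StageError` naming the
stage propagates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition_nca as nca
from . import orf_annotator as orf
from . import polyprotein_annotator as poly
from . import seqio
from .errors import DicistroError, LabelError, StageError

log = logging.getLogger("dicistro")


@dataclass
class RunConfig:
    """One reproducible run: inputs, thresholds, seed, output directory."""

    fasta: str | None = None
    labels: str | None = None
    query_fasta: str | None = None
    out_dir: str = "dicistro_out"
    min_aa: int = 100
    large_orf_min_nt: int = 300
    ridge: float = 1e-6
    feature_mode: str = "frequencies"
    priors: str = "equal"
    concordance_scheme: str = "resubstitution"
    seed: int = 0


def _stage(name: str, func, outputs: list[Path]):
    try:
        return func()
    except DicistroError as err:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise StageError(name, err) from err


def run_characterize(config: RunConfig) -> dict:
    """Annotate architecture, motifs and composition for one genome.

    Writes ``annotations.gff3``, ``segments.tsv``, ``motifs.tsv`` and
    ``composition.tsv`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log.info("characterize: fasta=%s seed=%d", config.fasta, config.seed)

    records = _stage("read_fasta", lambda: seqio.read_fasta(config.fasta), written)
    record = records[0]

    def detect():
        orfs = orf.find_orfs(
            record, min_aa=config.min_aa, strands="both"
        )
        return orf.detect_dicistronic(
            orfs, len(record), orf.DetectConfig(config.large_orf_min_nt)
        )

    arch = _stage("detect_dicistronic", detect, written)
    report = orf.segment_report(arch)

    prot1 = _stage("translate_orf1", lambda: orf.translate_orf(record, arch.orf1), written)
    prot2 = _stage("translate_orf2", lambda: orf.translate_orf(record, arch.orf2), written)

    catalogue = poly.DEFAULT_CATALOGUE
    orf1_cat = [p for p in catalogue if p.region != "capsid"]
    orf2_cat = [p for p in catalogue if p.region in ("capsid", "2A")]
    hits1, stray1 = poly.filter_short_motifs(poly.scan_motifs(prot1, orf1_cat))
    hits2, stray2 = poly.filter_short_motifs(poly.scan_motifs(prot2, orf2_cat))
    verdict = poly.check_module_order(hits1)
    repeats = poly.find_tandem_repeat(
        prot1, poly.MotifPattern("VPg-unit", "VPg", poly.VPG_UNIT_PATTERN)
    )

    profile = _stage(
        "composition_profile", lambda: nca.composition_profile(record), written
    )

    gff = out / "annotations.gff3"
    seqio.write_annotations(record, arch, hits1 + hits2, gff)
    written.append(gff)

    seg_tsv = out / "segments.tsv"
    lengths = arch.segment_lengths()
    pd.DataFrame(
        [
            {
                "segment": name,
                "nt_length": lengths[name],
                "aa_length": {"orf1": report.orf1_aa, "orf2": report.orf2_aa}.get(name, ""),
            }
            for name in ("utr5", "orf1", "igr", "orf2", "utr3")
        ]
    ).to_csv(seg_tsv, sep="\t", index=False)
    written.append(seg_tsv)

    motif_rows = [
        {
            "orf": 1 if h in hits1 else 2,
            "name": h.name,
            "region": h.region,
            "aa_start": h.aa_start,
            "matched": h.matched,
            "position_confirmed": h.position_confirmed,
        }
        for h in hits1 + hits2
    ]
    pd.DataFrame(motif_rows).to_csv(out / "motifs.tsv", sep="\t", index=False)
    written.append(out / "motifs.tsv")

    comp_rows = [
        {"feature": n, "frequency": v}
        for n, v in zip(nca.NUCLEOTIDES, profile.mono)
    ] + [
        {"feature": d, "frequency": profile.dinuc.ravel()[i],
         "oe_ratio": profile.oe.ravel()[i]}
        for i, d in enumerate(nca.DINUCLEOTIDES)
    ]
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t", index=False)
    written.append(out / "composition.tsv")

    result = {
        "record_id": record.id,
        "genome_length": len(record),
        "segments": lengths,
        "orf1_aa": report.orf1_aa,
        "orf2_aa": report.orf2_aa,
        "coding_fraction": report.coding_fraction,
        "noncoding_fraction": report.noncoding_fraction,
        "gc_percent": nca.gc_content(profile),
        "au_percent": nca.au_content(profile),
        "module_order_ok": verdict.ordered,
        "missing_regions": list(verdict.missing_regions),
        "npgp_found": verdict.npgp_found,
        "vpg_tandem_runs": [list(r.starts) for r in repeats],
        "reverse_large_orf": arch.reverse_large_orf,
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(result, indent=1))
    return result


def run_nca(config: RunConfig) -> dict:
    """Fit the host discriminant model on a labeled panel and classify queries.

    Writes ``model.json``, ``model_summary.json``, ``predictions.tsv`` and
    one ``ellipses_cf{i}{j}.tsv`` per canonical-factor pair.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log.info("nca: train=%s labels=%s seed=%d", config.fasta, config.labels, config.seed)

    records = _stage("read_fasta", lambda: seqio.read_fasta(config.fasta), written)
    labels_map = _stage("read_labels", lambda: seqio.read_labels(config.labels), written)
    orphans = [r.id for r in records if r.id not in labels_map]
    unmatched = sorted(set(labels_map) - {r.id for r in records})
    if orphans or unmatched:
        raise StageError(
            "match_labels",
            LabelError(
                f"unlabeled sequences: {orphans[:5]}; labels without sequence: "
                f"{unmatched[:5]}"
            ),
        )

    def featurize(recs):
        return np.vstack(
            [
                nca.build_features(nca.composition_profile(r), config.feature_mode)
                for r in recs
            ]
        )

    X = _stage("build_features", lambda: featurize(records), written)
    y = [labels_map[r.id] for r in records]
    model = _stage(
        "fit_cda",
        lambda: nca.fit_cda(X, y, ridge=config.ridge, priors=config.priors,
                            feature_mode=config.feature_mode),
        written,
    )
    conc = nca.concordance(
        X, y, scheme=config.concordance_scheme, ridge=config.ridge,
        priors=config.priors,
    )

    nca.save_model(model, out / "model.json")
    written.append(out / "model.json")

    Z = model.transform(X)
    predictions = []
    if config.query_fasta:
        queries = _stage(
            "read_query", lambda: seqio.read_fasta(config.query_fasta), written
        )
        Xq = _stage("featurize_query", lambda: featurize(queries), written)
        for rec, xq in zip(queries, Xq):
            pred = nca.classify(model, xq)
            row = {"id": rec.id, "predicted_host": pred.predicted}
            row.update({f"dist_{c}": s for c, s in pred.scores.items()})
            row.update(
                {f"CF{i+1}": v for i, v in enumerate(pred.canonical_coordinates)}
            )
            predictions.append(row)
        pd.DataFrame(predictions).to_csv(out / "predictions.tsv", sep="\t", index=False)
        written.append(out / "predictions.tsv")

    y_arr = np.asarray(y)
    ellipse_files = []
    for i, j in combinations(range(model.n_factors), 2):
        rows = []
        for cls in model.classes:
            pts = Z[y_arr == cls][:, [i, j]]
            if pts.shape[0] < 3:
                continue
            ell = nca.confidence_ellipse(pts, 0.95)
            rows.append(
                {
                    "host": cls,
                    "center_x": ell.center[0],
                    "center_y": ell.center[1],
                    "semi_major": ell.axes[0],
                    "semi_minor": ell.axes[1],
                    "angle_rad": ell.angle,
                    "level": ell.level,
                    "degenerate": ell.degenerate,
                }
            )
        fname = out / f"ellipses_cf{i+1}{j+1}.tsv"
        pd.DataFrame(rows).to_csv(fname, sep="\t", index=False)
        ellipse_files.append(fname.name)

    summary = {
        "classes": list(model.classes),
        "class_sizes": {c: int((y_arr == c).sum()) for c in model.classes},
        "eigenvalues": model.eigenvalues.tolist(),
        "concordance": conc,
        "concordance_scheme": config.concordance_scheme,
        "feature_mode": config.feature_mode,
        "ridge": config.ridge,
        "priors": config.priors,
        "seed": config.seed,
        "ellipse_files": ellipse_files,
        "predictions": [
            {"id": p["id"], "predicted_host": p["predicted_host"]}
            for p in predictions
        ],
    }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
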
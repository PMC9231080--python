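"""End-to-end helpers tying simulation, extraction, features and the classifier.

These are the programmatic counterparts of the CLI commands: simulate a
measurement campaign, push every record through denoising and
optical-constant extraction, assemble datasets, train and score a model.
The default problem sizes here are the desk-scale configuration: 20
classes, 5 tablets, a capped number of averaged records per tablet, and
the reduced 30 + 10 epoch training schedule at batch 16.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from thzamino import denoise as dn
from thzamino import eca_net, evaluation, features
from thzamino import extraction as ex
from thzamino import forward_model as fm

__all__ = [
    "FIG4_CLASSES",
    "simulate_records",
    "demo_training_config",
    "train_and_evaluate",
    "pca_silhouettes",
    "run_demo",
]

#: the 4-class subset used for the PCA clustering diagnostic
FIG4_CLASSES = ("Beta-Alanine", "D-Alanine", "D-Glutamic acid", "L-Glutamic acid")


def simulate_records(
    seed: int,
    *,
    classes: Sequence[str] | None = None,
    separable: bool = True,
    n_tablets: int = 5,
    duration_s: float = 40.0,
    avg_counts: Sequence[int] = (100, 20, 10),
    max_records_per_tablet: int | None = 2,
    instr: fm.InstrumentSpec | None = None,
    denoise_cfg: dn.DenoiseConfig | None = dn.DenoiseConfig(),
    n_echoes: int = 2,
    window: tuple[float, float] | None = (5.0, 10.0),
) -> tuple[dict[int, list[features.Record]], list[str]]:
    """Simulate a campaign and extract every record's optical constants.

    Returns ``(records per avg count, class names in library order)``.
    Each trace is gated around its main pulse (suppressing etalon echoes
    and late delay-line noise), wavelet-denoised, then inverted; the
    thickness used in the inversion is the nominal tablet thickness (the 1%
    tablet jitter is a realistic unknown).
    """
    instr = instr or fm.InstrumentSpec()
    library = fm.build_material_library(separable=separable)
    if classes is not None:
        wanted = set(classes)
        library = [m for m in library if m.name in wanted]
        missing = wanted - {m.name for m in library}
        if missing:
            raise ValueError(f"unknown classes: {sorted(missing)}")
    class_names = [m.name for m in library]

    traces = fm.acquire_dataset(
        library,
        instr,
        n_tablets=n_tablets,
        duration_s=duration_s,
        avg_counts=avg_counts,
        seed=seed,
        n_echoes=n_echoes,
        max_records_per_tablet=max_records_per_tablet,
    )
    ref = fm.simulate_reference(
        instr, seed=seed + 10_000, n_averaged=instr.reference_averages
    )

    def prepare(trace):
        if window is not None:
            trace = ex.window_main_pulse(trace, *window)
        if denoise_cfg is not None:
            trace = dn.wavelet_denoise(trace, denoise_cfg)
        return trace

    ref = prepare(ref)
    d_nominal = library[0].thickness_d
    records: dict[int, list[features.Record]] = {}
    for avg, group in traces.items():
        out = []
        for trace in group:
            oc = ex.extract_optical_constants(prepare(trace), ref, d_nominal)
            out.append(
                features.Record(
                    label=trace.label, tablet_id=trace.tablet_id, alpha=oc.alpha, n=oc.n
                )
            )
        records[avg] = out
    return records, class_names


def demo_training_config(full: bool = False, batch_size: int = 16) -> eca_net.TrainingConfig:
    """The reduced 30 + 10 epoch schedule (or the full 300 + 100 one).

    The reduced schedule scales batch size and early-stopping patience with
    the epoch budget (16 and 3, i.e. the same 10% patience-to-epochs ratio
    as the full 30/300 protocol).
    """
    if full:
        return eca_net.TrainingConfig()
    return eca_net.TrainingConfig(
        epochs=30, fine_tune_epochs=10, batch_size=batch_size, patience=3
    )


def ablation_sweep(
    seeds: Sequence[int],
    *,
    max_records_per_tablet: int = 1,
    tcfg: eca_net.TrainingConfig | None = None,
) -> list[dict]:
    """Train {hybrid, absorption, refractive} x ECA plus the plain CNN for
    each seed on the separable library; returns one result row per seed with
    every model's split accuracies."""
    rows = []
    for seed in seeds:
        records, names = simulate_records(
            seed, separable=True, max_records_per_tablet=max_records_per_tablet
        )
        row = {"seed": seed, "accuracy": {}}
        for mode, eca in (
            ("hybrid", True),
            ("absorption", True),
            ("refractive", True),
            ("plain_cnn", False),
        ):
            res = train_and_evaluate(
                records,
                names,
                input_mode="hybrid" if mode == "plain_cnn" else mode,
                use_eca=eca,
                seed=seed,
                tcfg=tcfg,
            )
            row["accuracy"][mode] = res["accuracy"]
        rows.append(row)
    return rows


def train_and_evaluate(
    records: dict[int, list[features.Record]],
    class_names: Sequence[str],
    *,
    input_mode: str = "hybrid",
    use_eca: bool = True,
    seed: int = 0,
    tcfg: eca_net.TrainingConfig | None = None,
    test_avgs: Sequence[int] = (20, 10),
) -> dict:
    """Assemble datasets, train one model, and evaluate every split."""
    tcfg = tcfg or demo_training_config()
    splits = features.assemble_datasets(
        records,
        input_mode=input_mode,
        seed=seed,
        test_avgs=test_avgs,
        class_names=class_names,
    )
    train_set, val_set = splits[0], splits[1]
    cfg = eca_net.NetworkConfig(
        n_classes=len(class_names),
        input_channels=train_set.X.shape[2],
        use_eca=use_eca,
    )
    model = eca_net.build_network(cfg, seed=seed)
    model, history = eca_net.train(model, train_set, val_set, tcfg, seed=seed)
    reports = {s.split_tag: evaluation.evaluate(model, s) for s in splits}
    return {
        "model": model,
        "history": history,
        "reports": reports,
        "accuracy": {tag: r.accuracy for tag, r in reports.items()},
        "input_mode": input_mode,
        "use_eca": use_eca,
        "seed": seed,
    }


def _standardized_items(recs: list[features.Record], columns) -> list[np.ndarray]:
    stack = np.stack([np.column_stack([r.alpha, r.n]) for r in recs])
    mean = stack.reshape(-1, 2).mean(axis=0)
    std = stack.reshape(-1, 2).std(axis=0)
    std[std == 0] = 1.0
    return [((m - mean) / std)[:, columns] for m in stack]


def pca_silhouettes(
    seed: int,
    classes: Sequence[str] = FIG4_CLASSES,
    separable: bool = False,
) -> dict[str, float]:
    """Silhouette scores of the three PCA embeddings on per-tablet spectra.

    Each point is one tablet's full-campaign average (all raw acquisitions
    of the tablet averaged into a single record).  'hybrid' uses the first
    principal component of the flattened Nx2 spectrum; 'absorption' and
    'refractive' use the first two components of the single metric.
    """
    instr = fm.InstrumentSpec()
    total = int(instr.acquisition_rate * 40.0)
    records, _ = simulate_records(
        seed,
        classes=classes,
        separable=separable,
        avg_counts=(total,),
        max_records_per_tablet=1,
    )
    recs = records[total]
    labels = [r.label for r in recs]
    out: dict[str, float] = {}
    hybrid_items = _standardized_items(recs, [0, 1])
    scores1 = features.first_principal_component(
        [features.HybridSpectrum(m) for m in hybrid_items]
    )
    out["hybrid"] = float(silhouette_score(scores1.reshape(-1, 1), labels))
    for name, col in (("absorption", 0), ("refractive", 1)):
        items = _standardized_items(recs, [col])
        scores2 = features.principal_scores(items, n_components=2)
        out[name] = float(silhouette_score(scores2, labels))
    return out


def run_demo(
    seed: int = 1,
    *,
    use_eca: bool = True,
    full: bool = False,
    max_records_per_tablet: int = 3,
) -> dict:
    """Scaled-down end-to-end run: simulate (separable library), extract,
    train hybrid and single-metric models, evaluate on the noisier
    average-20 / average-10 analogues.  Returns a JSON-serializable report."""
    records, class_names = simulate_records(
        seed, separable=True, max_records_per_tablet=max_records_per_tablet
    )
    tcfg = demo_training_config(full=full)
    rows = {}
    for mode in ("hybrid", "absorption", "refractive"):
        res = train_and_evaluate(
            records,
            class_names,
            input_mode=mode,
            use_eca=use_eca,
            seed=seed,
            tcfg=tcfg,
        )
        rows[mode] = res
    main = rows["hybrid"]
    report = {
        "seed": seed,
        "use_eca": use_eca,
        "class_names": list(class_names),
        "accuracy": {
            mode: res["accuracy"] for mode, res in rows.items()
        },
        "per_class_test10": dict(
            zip(class_names, main["reports"]["test10"].per_class)
        ),
        "ablation_ordering_test10": sorted(
            ((res["accuracy"]["test10"], mode) for mode, res in rows.items()),
            reverse=True,
        ),
        "n_parameters": main["model"].n_parameters(),
    }
    report["models"] = {mode: res["model"] for mode, res in rows.items()}
    return report
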
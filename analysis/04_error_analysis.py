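"""Error analysis and track comparison.

Two parts:

1. Synthetic tracks: compares the few-shot and fine-tuned metrics produced
   by 02/03 per overlap condition.  Note this contrasts the *protocols*, not
   the published models: the mock scorer reads the generating lexicon
   directly, so on synthetic data the few-shot track is a ceiling, not the
   weaker baseline it is with real language models.  What carries over is
   the error structure — both tracks degrade by confusing the
   {major, atypical, bipolar} block as vocabulary overlap grows.
2. Published benchmark: recomputes, from the transcribed tables and in-text
   confusion counts, the best-vs-best deltas (+19.2 pp macro-F1, +20.4 pp
   accuracy) and the bipolar-centred precision/recall arithmetic for both
   best models.

Writes results/track_comparison.csv and results/published_arithmetic.json.
"""

import json
from pathlib import Path

import pandas as pd

from subtypebench.corpus import SubtypeLabel
from subtypebench.evaluation import as_percent, compare_best, load_published_fixtures

ROOT = Path(__file__).resolve().parent.parent / "results"
_L = SubtypeLabel


def synthetic_comparison() -> None:
    fewshot = pd.read_csv(ROOT / "fewshot_metrics.csv")
    finetune = pd.read_csv(ROOT / "finetune_metrics.csv")
    merged = fewshot.merge(finetune, on="overlap", suffixes=("_fewshot", "_finetune"))
    merged["delta_macro_f1_pp"] = 100 * (
        merged["test_macro_f1"] - merged["macro_f1"]
    )
    merged.to_csv(ROOT / "track_comparison.csv", index=False)
    for _, row in merged.iterrows():
        print(
            f"overlap={row['overlap']}: few-shot macro-F1 {row['macro_f1']:.3f} "
            f"vs fine-tuned {row['test_macro_f1']:.3f} "
            f"(delta {row['delta_macro_f1_pp']:+.1f} pp)"
        )


def published_arithmetic() -> None:
    fx = load_published_fixtures()
    best_ft, best_fs, delta_f1 = compare_best(fx.benchmark, "macro_f1", "test")
    _, _, delta_acc = compare_best(fx.benchmark, "accuracy", "test")
    out = {
        "best_fine_tuned": best_ft["model"],
        "best_few_shot": best_fs["model"],
        "delta_test_macro_f1_pp": round(delta_f1, 1),
        "delta_test_accuracy_pp": round(delta_acc, 1),
        "prompt_only": {
            "bipolar_recall_pct": as_percent(fx.prompt_only.recall(_L.BIPOLAR)),
            "bipolar_precision_pct": as_percent(fx.prompt_only.precision(_L.BIPOLAR)),
            "nodep_to_bipolar_pct": as_percent(
                fx.prompt_only.misclassification_rate(_L.NO_DEPRESSION, _L.BIPOLAR)
            ),
            "atypical_to_bipolar_pct": as_percent(
                fx.prompt_only.misclassification_rate(_L.ATYPICAL, _L.BIPOLAR)
            ),
            "major_recall_pct": as_percent(fx.prompt_only.recall(_L.MAJOR)),
        },
        "fine_tuned": {
            "bipolar_recall_pct": as_percent(fx.fine_tuned.recall(_L.BIPOLAR)),
            "bipolar_precision_pct": as_percent(fx.fine_tuned.precision(_L.BIPOLAR)),
            "nodep_to_bipolar_pct": as_percent(
                fx.fine_tuned.misclassification_rate(_L.NO_DEPRESSION, _L.BIPOLAR)
            ),
            "major_recall_pct": as_percent(fx.fine_tuned.recall(_L.MAJOR)),
        },
    }
    (ROOT / "published_arithmetic.json").write_text(json.dumps(out, indent=2))
    print(
        f"published best-vs-best: {out['best_fine_tuned']} over "
        f"{out['best_few_shot']}: {out['delta_test_macro_f1_pp']:+.1f} pp macro-F1, "
        f"{out['delta_test_accuracy_pp']:+.1f} pp accuracy"
    )


def main() -> None:
    synthetic_comparison()
    published_arithmetic()


if __name__ == "__main__":
    main()
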
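"""Generate the synthetic study corpora and their stratified splits.

Produces three seeded corpora at the benchmark's class proportions with
increasing vocabulary overlap inside the confusable {major, atypical,
bipolar} triple (0.0, 0.5, 0.9), deduplicates, splits 80/10/10, and writes
corpora + split manifests under results/data/.
"""

import json
from pathlib import Path

from subtypebench.corpus import LABEL_ORDER, class_counts, stratified_split, write_corpus
from subtypebench.synthetic import GeneratorConfig, generate_corpus

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260929
N_TOTAL = 1200
OVERLAPS = (0.0, 0.5, 0.9)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for overlap in OVERLAPS:
        config = GeneratorConfig(
            n_total=N_TOTAL,
            overlap=overlap,
            noise_rate=0.1,
            url_mention_rate=0.1,
            seed=SEED,
        )
        corpus, _ = generate_corpus(config)
        tag = f"overlap{overlap:.1f}"
        write_corpus(corpus, OUT / f"corpus_{tag}.jsonl")
        bundle = stratified_split(corpus, (0.8, 0.1, 0.1), seed=SEED)
        for name, part in [
            ("train", bundle.train),
            ("val", bundle.validation),
            ("test", bundle.test),
        ]:
            write_corpus(part, OUT / f"{tag}_{name}.jsonl")
        manifest = {
            "overlap": overlap,
            "seed": SEED,
            "n_total": N_TOTAL,
            "class_counts": {
                l.label_name: int(c) for l, c in zip(LABEL_ORDER, class_counts(corpus))
            },
            "split_sizes": {
                "train": len(bundle.train),
                "val": len(bundle.validation),
                "test": len(bundle.test),
            },
        }
        (OUT / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=2))
        print(
            f"overlap={overlap}: {len(corpus)} examples, "
            f"splits {manifest['split_sizes']}"
        )


if __name__ == "__main__":
    main()
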
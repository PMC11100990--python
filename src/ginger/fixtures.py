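"""Deterministic synthetic asset generation: the full stimulus set, a small
trained beta-VAE, an email corpus, and golden expected-output tables for the
worked examples.  Everything is derived from one seed."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CSV_FLOAT_FORMAT
from .representations import (BVAESpec, generate_synthetic_emails,
                              render_stimulus, train_bvae)
from .runner import all_stimulus_specs, derive_seed

__all__ = ["make_fixtures"]


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Generate and serialize the packaged synthetic assets; bit-identical
    per seed.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 27 full-factor stimuli (plus the partial-factor variants used by the
    # transfer task's early phases)
    specs = all_stimulus_specs()
    full = [s for s in specs if s.color is not None and s.texture is not None]
    images = [render_stimulus(s) for s in specs]
    np.savez_compressed(out / "stimuli.npz",
                        **{f"img_{i}": im for i, im in enumerate(images)})
    stim_manifest = [
        {"index": i, "shape": s.shape, "color": s.color, "texture": s.texture}
        for i, s in enumerate(specs)
    ]

    # small trained beta-VAE over all renders
    bvae_spec = BVAESpec(seed=derive_seed(seed, 0))
    model = train_bvae(images, bvae_spec)
    np.savez_compressed(out / "bvae_weights.npz",
                        **{f"p{i}": p for i, p in enumerate(model._params())})
    bvae_meta = {
        "latent_dim": bvae_spec.latent_dim,
        "beta": bvae_spec.beta,
        "hidden_dim": bvae_spec.hidden_dim,
        "epochs": bvae_spec.epochs,
        "seed": bvae_spec.seed,
        "initial_loss": model.loss_history[0]["loss"],
        "final_loss": model.loss_history[-1]["loss"],
    }
    (out / "bvae_meta.json").write_text(json.dumps(bvae_meta, indent=2))

    # synthetic email corpus (32-dim embeddings for compactness)
    emails = generate_synthetic_emails(n=239, embedding_dim=32,
                                       seed=derive_seed(seed, 1))
    rows = []
    for e in emails:
        row = {"id": e.id, "label": e.label, **e.features}
        row.update({f"e{j}": v for j, v in enumerate(e.embedding.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "emails.csv", index=False,
                              float_format=CSV_FLOAT_FORMAT)

    # golden worked examples of the core quantities
    golden = pd.DataFrame([
        {"quantity": "activation_single_lag1", "value": 0.0},
        {"quantity": "activation_lags_1_and_4", "value": math.log(1 + 4 ** -0.5)},
        {"quantity": "softmax_0_ln2_tau1_p2", "value": 2.0 / 3.0},
        {"quantity": "blend_p13_p23_u01", "value": 2.0 / 3.0},
        {"quantity": "kl_unit_var_means_0_1", "value": 0.5},
        {"quantity": "cosine_10_11", "value": 1.0 / math.sqrt(2.0)},
        {"quantity": "bic_n4_rss8_k1", "value": 4 * math.log(2.0) + math.log(4.0)},
    ])
    golden.to_csv(out / "golden_examples.csv", index=False,
                  float_format=CSV_FLOAT_FORMAT)

    manifest = {
        "seed": seed,
        "stimuli": stim_manifest,
        "n_full_factor_stimuli": len(full),
        "bvae": bvae_meta,
        "corpus_size": len(emails),
        "files": ["stimuli.npz", "bvae_weights.npz", "bvae_meta.json",
                  "emails.csv", "golden_examples.csv"],
    }
    (out / "fixtures_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    return manifest
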
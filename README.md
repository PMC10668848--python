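# openherd

Open-set recognition of individual animals from face images: margin-softmax
classification plus reciprocal-point open-space scoring, with a procedural
synthetic-herd generator and the full open-set evaluation protocol
(CSA, AUROC, OSCR, closed-set Acc/F1, openness sweeps).

## The problem

Camera-based livestock monitoring needs to tell individual animals apart
from face images. Closed-set classifiers silently mislabel any animal that
was not in the training herd; in practice new (unregistered, "unknown")
animals join herds all the time. Open-set recognition (OSR) asks the model
to classify images of *known* individuals **and** reject images of
*unknown* ones — on herds where all faces share breed-level appearance and
identity hides in subtle markings.

## The method

A feature extractor `f(x)` feeds two jointly trained heads:

* an **AM-Softmax** head — cross-entropy on `s`-scaled cosine logits with an
  additive margin `m` on the correct class (`s = 10`, `m = 0.5`) — giving
  compact, well-separated known classes;
* a **reciprocal-point** head: one learnable point `P_k` and margin `R_k`
  per known class, with combined distance
  `d(f, P_k) = ‖f − P_k‖²/dim − f·P_k`, a distance-softmax cross-entropy
  that positions the points, and the adversarial margin constraint
  `L_AMC = max(d_e(f, P_k) − R_k, 0)` bounding open-space risk.

The **known-ness score** of a test image is `max_k d(f(x), P_k)`; unknowns
are rejected below a threshold `τ`, and the threshold-free metrics
(AUROC, OSCR) sweep `τ`. See `docs/methods.md` for the full model,
defaults, and design rationale.

Since the real herd datasets this method targets are not public, the
package ships a procedural generator: per-identity face-like textures with
a controllable identity-separability dial (`sigma_id`) and the nuisance
factors of uncontrolled capture (pose, illumination, fog, partial faces,
occlusion, head size).

## Worked example

```bash
openherd run --out runs/demo
```

generates a 17-individual synthetic herd (two days, three feeding sessions,
24 images per individual per session, 64 px, identity-separability
`sigma_id = 1.0`), trains five random 10-known/7-unknown splits for 20
epochs each, evaluates on the held-out day, and prints the aggregate
(about 12 minutes on one CPU):

```json
{
  "n_trials": 5,
  "sd_convention": "sample",
  "mean": {"csa": 93.44, "auroc": 84.76, "oscr": 81.52},
  "sd":   {"csa": 4.99,  "auroc": 8.03,  "oscr": 10.15},
  ...
}
```

`csa` is closed-set accuracy over known test images (percent); `auroc` the
known-vs-unknown ranking quality of the known-ness score; `oscr` the area
under the correct-classification-rate vs false-positive-rate curve — a
single number combining both tasks (always ≤ `csa`). At the default
moderate herd similarity, individual trials range widely (AUROC 77–96 here)
— open-set difficulty depends on which individuals happen to be unknown.
At the well-separated operating point (`sigma_id: 2.0` in the `synthetic:`
config block) the same protocol reaches CSA ≈ 99 / AUROC ≈ 97. Per-trial
score tables, checkpoints, loss logs and metrics land in
`runs/demo/trial_*/`.

The same library surface is importable (`openherd.make_identities`,
`openherd.train`, `openherd.auroc`, ...), and further subcommands cover the
pieces: `generate-data`, `train`, `evaluate`, `sweep-openness` (fixed
unknowns, shrinking knowns — the openness ladder), `report`.

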
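"""Compare training strategies on a heterogeneous 5-site federation.

Local-only models see one site's distribution and degrade on the global
test set; FedAvg and the federated hypernetwork learn from every site
without moving data; the centralized model is the privacy-free upper
bound.  (Two replicate seeds here for speed; the acceptance script runs
five.)
"""

from fedmil.experiments import ordering_experiment

res = ordering_experiment(seed=0, n_seeds=2)
print("global-test AUC (mean +/- std over seeds):")
for arm in ("local_worst", "local_only", "fedavg", "fedhn", "centralized"):
    label = {"local_only": "best single site", "local_worst": "worst single site"}.get(arm, arm)
    print(f"  {label:>18}: {res.auc_mean[arm]:.3f} +/- {res.auc_std[arm]:.3f}")
# Expected ordering: single-site models < fedavg, fedhn <= centralized.
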
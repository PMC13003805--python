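"""Train the two-stage CBV/VSD estimator on a small simulated dataset.

A desk-scale version of the full pipeline: a few hundred volumes of
interest are generated and simulated, the CBVE (signal ratio → CBV) is
trained first, then frozen while the VSDE (signal ratio + predicted CBV →
40-bin VSD) trains.  Held-out performance is compared against best-R²
dictionary matching on the same split.  Expect a few minutes on one CPU;
accuracy at this tiny scale is below the full-study numbers.
"""

import numpy as np

from vsdprint.baselines import Dictionary, dictionary_match_batch
from vsdprint.evaluation import bhattacharyya, mre, pearson
from vsdprint.experiments import StudyConfig, generate_study_vois
from vsdprint.gesfide import SimulationConfig, simulate_gesfide_batch
from vsdprint.models import ModelSpec, filter_and_split, predict, train_two_stage

cfg = StudyConfig(
    n_vois=600,
    sim=SimulationConfig(dt=2.5e-3),
    model=ModelSpec(max_epochs=80, patience=80),
)
occ, cbv, vsd = generate_study_vois(cfg, seed=3)
signals = simulate_gesfide_batch(occ, cfg.sim_grid, cfg.sim)
ds = filter_and_split(signals, cbv, vsd, seed=3)
print("partition:", ds.counts())

models = train_two_stage(ds, cfg.model, seed=3)
x_test, cbv_test, vsd_test = ds.split("test")
pred_cbv, pred_vsd = predict(models, x_test)
bc = np.mean([bhattacharyya(t, p) for t, p in zip(vsd_test, pred_vsd)])
print(
    f"estimator : r(CBV)={pearson(cbv_test, pred_cbv):.3f}  "
    f"MRE={mre(cbv_test, pred_cbv):.1f}%  mean BC={bc:.3f}"
)

x_train, cbv_train, vsd_train = ds.split("train")
d_cbv, d_vsd, _ = dictionary_match_batch(x_test, Dictionary(x_train, cbv_train, vsd_train))
bc_d = np.mean([bhattacharyya(t, p) for t, p in zip(vsd_test, d_vsd)])
print(
    f"dictionary: r(CBV)={pearson(cbv_test, d_cbv):.3f}  "
    f"MRE={mre(cbv_test, d_cbv):.1f}%  mean BC={bc_d:.3f}"
)
# r: linear agreement of predicted with true blood volume; MRE: mean relative
# CBV error; BC: similarity of predicted and true vessel size distributions
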
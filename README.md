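# arcticiso

Isoprene emission modelling for Arctic and boreal ecosystems: the MEGANv2.1
temperature activity factor, acclimating response curves for tundra sedges
(*Carex*, *Eriophorum*) and willow shrubs (*Salix*), Arrhenius fitting of
leaf-chamber temperature ramps, plant-functional-type mixture fitting of
eddy-covariance site fluxes, and long-term trend analysis — all exercisable
end-to-end on seeded synthetic data.

## The scientific problem

Isoprene (C₅H₈) is the most abundant reactive biogenic VOC. Standard emission
models describe its temperature response with a curve measured on temperate
plants, whose Q10 — the factor by which emission grows per 10 °C of leaf
warming — is about 3. Ecosystem-scale measurements in high-latitude tundra
instead show Q10 values above 8. The resolution is that Arctic sedges follow
a purely exponential short-term response whose Arrhenius activation energy
acclimates to the mean air temperature of the previous 10 days (T240):

```
γ_T_sg   = E_opt_sg · exp( C_sg/R · (1/303.15 − 1/T) )
C_sg     = 95 + 9.5·exp( 0.53·(288.15 − T240) )        [kJ mol⁻¹]
E_opt_sg = exp( 0.12·(T240 − 288.15) )
```

Cold-acclimated sedges have very high activation energy but low emission
capacity, and vice versa — an inverse Ea–EF relationship. Willows keep the
default peaked MEGAN curve (activation/deactivation energies CT1 = 95,
CT2 = 230 kJ mol⁻¹, optimum T_opt = 313 + 0.6·(T240 − 297.15) K) but with a
stronger long-term capacity response, E_opt = 7.9·exp(0.22·(T24 − 297.15)).

At a site, the half-hourly flux is a mixture over vegetation types i:

```
F = Σᵢ  ε*ᵢ · CFᵢ · (LAI/LAI_max) · γ_T_i · γ_others
```

with canopy emission factors ε*ᵢ scaled from leaf level (×5·Cce = ×1.5) and
cover fractions CFᵢ recovered by bounded least squares against
eddy-covariance observations (daytime filter PPFD > 300 µmol m⁻² s⁻¹).

## Worked example

```python
import numpy as np
from arcticiso import *

for t240 in (282.15, 284.15, 286.15, 288.15):
    qq = q10(lambda T: gamma_t_sedge(TemperatureHistory(T, t240, t240)))
    print(f"T240={t240-273.15:5.1f} C  C_sg={float(c_sg(t240)):6.1f} kJ/mol  "
          f"E_opt_sg={float(e_opt_sg(t240)):.3f}  Q10={qq:6.1f}")

curve = lambda T: gamma_t_default(TemperatureHistory(T, 297.15, 297.15))
print("default MEGAN Q10:", round(q10(curve), 3))

exp = gen_chamber(SyntheticConfig(seed=7))[0]          # one 15→40 °C ramp
fit = fit_arrhenius(exp)                               # log-space Arrhenius
print(f"Ea={fit.ea:.1f} kJ/mol, EF30={fit.ef30:.2f} nmol/m2/s, "
      f"R2={fit.r_squared:.4f}, n={fit.n_points}")

series, truth = gen_site(SyntheticConfig(seed=7), n_days=60)
pfts = [SitePFT("sedge", 12.0, "sedge"), SitePFT("willow_shrub", 6.5, "willow")]
res = fit_cover_fractions(series, pfts)
print("fitted CFs:", np.round(res.cover_fractions, 3),
      f"R2={res.r_squared:.3f} RMSE={res.rmse:.3f} n={res.n_obs}")
```

prints

```
T240=  9.0 C  C_sg= 323.4 kJ/mol  E_opt_sg=0.487  Q10=  69.0
T240= 11.0 C  C_sg= 174.1 kJ/mol  E_opt_sg=0.619  Q10=   9.8
T240= 13.0 C  C_sg= 122.4 kJ/mol  E_opt_sg=0.787  Q10=   5.0
T240= 15.0 C  C_sg= 104.5 kJ/mol  E_opt_sg=1.000  Q10=   3.9
default MEGAN Q10: 2.977
Ea=118.6 kJ/mol, EF30=9.23 nmol/m2/s, R2=0.9999, n=5
fitted CFs: [0.248 0.102] R2=0.996 RMSE=0.017 n=1524
```

Reading this: a sedge canopy that has experienced a 9 °C ten-day mean is in
the hyper-sensitive regime (Q10 ≈ 69, far above the default model's 2.98)
but emits little at 30 °C (capacity multiplier 0.49); at a 15 °C mean it has
relaxed to near-default sensitivity with full capacity. The chamber fit
recovers the per-plant activation energy from the ramp steps at or below
35 °C (the 40 °C step is excluded; the exponential regime degrades there),
and the site fit recovers the generating cover fractions 0.25/0.10 to within
±0.003 from 60 days of noisy half-hourly flux.

## Command line

```sh
arcticiso synth site --seed 4 --n-days 30 --out data/       # synthetic fixtures
arcticiso fit-chamber --input data/chamber.csv --history data/chamber_history.csv \
    --tmax-c 35 --out fits.csv
arcticiso fit-site --flux data/site.csv --config site.toml --mode fit-cf \
    --ppfd-min 300 --out fit.json
arcticiso simulate --met data/site.csv --config site.toml --model updated --out flux.csv
arcticiso trend --met data/site.csv --config site.toml --out trend.json
```

Every run writes a JSON manifest (inputs digests, options, seed, version)
beside its output. Configuration is TOML; see `docs/methods.md` for the
schema and parameter meanings.

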
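# riflow

Reproductive isolation (RI), quantified as a reduction in gene flow.

Speciation research uses "reproductive isolation" in two senses: an
organismal one (how much less often do the taxa interbreed, how unfit are
their hybrids?) and a genetic one (how much is gene flow between their gene
pools reduced?).  `riflow` implements the genetic definition and the
machinery that connects the two, for population geneticists and
evolutionary biologists who want to

- **simulate** how divergently selected loci, epistatic incompatibilities
  and physical dispersal barriers impede neutral gene flow, in a two-deme
  setting and across a one-dimensional hybrid zone;
- **predict** that impediment with the classical closed-form results of
  migration–selection–recombination theory; and
- **estimate** it from the kinds of data empiricists actually collect:
  mating counts, hybrid-class fitnesses, allele-frequency transects, F_ST.

## The quantities

**Two demes.**  With migration rate *m* (fraction of the focal deme replaced
by migrants per generation), a neutral allele actually enters the recipient
gene pool at the *effective migration rate*

    m_e = δp / Δp ,

the per-generation allele-frequency change δp relative to the between-deme
difference Δp.  Reproductive isolation at that locus is

    RI = 1 − m_e / m .

RI = 0 means no barrier, RI = 1 complete isolation, and RI < 0 is possible
(heterosis, adaptive introgression).  For a marker unlinked to all selected
loci, `m_e/m` equals the product of mean fitnesses of migrants, F1s and
successive backcrosses, `W̄0·W̄1·W̄2·…` (roughly `W̄0·W̄1·W̄2²`); for a marker
linked at recombination fraction *r* to one selected locus with coefficient
*s*,

    RI = 1 − r / (s + r) ,

and for two flanking selected loci

    RI = 1 − [r1/(r1+s1)]·[r2/(r2+s2)]·[(r1+r2+s1+s2)/(r1+r2+s12)] .

**Hybrid zone.**  In continuous space the barrier is a distance: the
*barrier strength*

    B = Δp / p′

(central allele-frequency step over flanking gradient) is the extra habitat
length that would impede diffusion as much as the zone does.  Analytically,

    B = ∫ [ (W̄(x)/W̄0)^(−1/r) − 1 ] dx ,

with W̄(x) the mean fitness across the zone and *r* the harmonic-mean
recombination fraction to the selected loci; and for a bounded,
long-established zone the two sides behave like two demes exchanging at

    m_e ≈ σ² / (2 B X) .

**Empirical estimators.**  Prezygotic index `1 − H/C`; the
Sobel–Chen index `(1 − H/C)/(1 + H/C)`; sequential combination of barrier
components (total `1 − Π(1−RI_i)`); three-part stepped-cline fits
(gradient – step – gradient) of transect data yielding Δp, p′ and per-side
B; and the island-model conversion `N_e·m_e = (1/F_ST − 1)/4`.

## Worked example

A neutral marker at recombination fraction r = 0.1 from one locus under
divergent selection (s = 0.1), migration m = 1e-4:

```python
from riflow import *

arch = GeneticArchitecture([divergent_locus("sel", 0.1), Locus("neu")], [0.1])
scheme = FitnessScheme(arch)
traj = simulate_two_deme(arch, scheme, TwoDemeConfig(m=1e-4))
me = effective_migration_rate(traj, "neu")
print(f"m_e = {me:.3e}")
print(f"RI  = {ri_two_deme(me, 1e-4).ri:.4f}")
```

prints

```
m_e = 4.738e-05
RI  = 0.5262
```

— selection at the linked locus halves effective gene flow, close to the
closed-form prediction RI = 1 − r/(s+r) = 0.5 (the deterministic
discrete-generation model sits slightly above the diffusion-limit formula).

The same barrier in space: a 200-deme stepped-stone zone with nearest-
neighbour exchange m = 0.5, divergent selection s = 0.2, and a neutral
marker at r = 0.01:

```python
cfg = ZoneConfig(n_demes=200, m=0.5)
arch = zone_architecture(0.2, 0.01)
res = simulate_zone(arch, FitnessScheme(arch), cfg, 1600, record_at=[800, 1600])
for g in (800, 1600):
    b = measure_barrier(res.profile(g, "neu"), center=cfg.step_interface,
                        sigma=cfg.sigma)
    print(f"generation {g}: B = {b.b:.1f} deme spacings ({b.b_sigma:.1f} sigma units)")
```

```
generation 800: B = 25.2 deme spacings (35.7 sigma units)
generation 1600: B = 24.6 deme spacings (34.8 sigma units)
```

— the neutral cline keeps flattening, but B is already stable (within 2.5%
over a doubling of the zone's age): the barrier is a property of the zone,
not of the transient allele frequencies.

A command-line surface wraps the same functions:

```sh
riflow ri-profile --config cfg.yaml --r-grid 0.001,0.01,0.1,0.5 --out ri.tsv
riflow simulate-zone --config zone.yaml --out profiles.tsv
riflow measure-barrier --in profiles.tsv --center auto --out barrier.tsv
riflow fit-cline --in transect.tsv --out fit.json
riflow ri-organismal --mode sobel-chen --in matings.tsv
riflow make-fixture --spec fixture.yaml --out transect.tsv
```

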
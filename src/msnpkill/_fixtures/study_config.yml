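# Default study configuration: 1 mg of acetylated MSNPs per dose on four
# treatment days, silicon at 39.36% of particle mass.  Organ reference
# masses are BALB/c strain-standard values (grams); tumor mass assumes
# ~500 mm^3 at unit density.  Control baselines are nominal trace Si mass
# percentages in untreated tissue; override per study.
particle_mass_per_dose_mg: 1.0
n_doses: 4
si_fraction: 0.3936
organ_reference_masses:
  tumor: 0.5
  liver: 1.0
  spleen: 0.1
  kidney: 0.3
control_baseline:
  tumor: 0.0005
  liver: 0.0008
  spleen: 0.0008
  kidney: 0.0006
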
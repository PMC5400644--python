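# Default radionuclide registry.
#
# half_life_h   : physical half-life in hours
# daughter_z    : atomic number of the decay daughter (Coulomb correction of
#                 the beta spectrum)
# branches      : beta-minus branches, each with the endpoint energy in keV
#                 and the branch fraction per decay.  Following standard
#                 printed summaries, each therapeutic nuclide ships its single
#                 dominant endpoint at fraction 1.0; full decay schemes can be
#                 supplied through a user registry file.
#
# In-111 decays by electron capture (gamma lines 171/245 keV used for
# counting and imaging only) and therefore carries no beta branches.
In-111:
  half_life_h: 67.2        # 2.80 d
  daughter_z: 48           # Cd-111
  branches: []
Lu-177:
  half_life_h: 161.52      # 6.73 d
  daughter_z: 72           # Hf-177
  branches:
    - emax_kev: 490.0
      fraction: 1.0
Y-90:
  half_life_h: 64.08       # 2.67 d
  daughter_z: 40           # Zr-90
  branches:
    - emax_kev: 2290.0
      fraction: 1.0
I-131:
  half_life_h: 192.72      # 8.03 d
  daughter_z: 54           # Xe-131
  branches:
    - emax_kev: 606.0
      fraction: 1.0
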
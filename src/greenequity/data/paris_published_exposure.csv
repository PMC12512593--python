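category,subcategory,population,pm25_baseline,pm25_scenario,pm25_delta,tree_ha_baseline,tree_ha_scenario,tree_ha_delta
age,<18,,15.28,15.18,-0.099,4.72,5.01,0.28
age,18-64,,15.32,15.18,-0.136,4.52,4.93,0.41
age,>=65,,15.28,15.14,-0.133,4.73,5.10,0.38
citizenship,citizen,,15.29,15.16,-0.130,4.63,5.02,0.39
citizenship,non-citizen,,15.38,15.27,-0.113,4.42,4.75,0.34
education,primary,,15.34,15.25,-0.093,4.59,4.84,0.25
education,secondary,,15.28,15.18,-0.098,4.74,5.01,0.27
education,tertiary,,15.31,15.14,-0.169,4.47,5.01,0.54
employment,unemployed,,15.35,15.23,-0.124,4.48,4.85,0.36
employment,employed,,15.31,15.17,-0.140,4.52,4.95,0.44
income,bottom quintile,,15.46,15.41,-0.059,4.55,4.66,0.12
income,middle quintiles,,15.22,15.09,-0.132,4.57,4.96,0.39
income,top quintile,,15.33,15.11,-0.211,4.69,5.42,0.73
total,total,,15.30,15.18,-0.127,4.60,4.98,0.38
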
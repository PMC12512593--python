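category,subcategory,population,pm25_baseline,pm25_scenario,pm25_delta,tree_ha_baseline,tree_ha_scenario,tree_ha_delta
age,<18,,10.61,10.58,-0.028,3.22,3.52,0.30
age,18-64,,10.65,10.61,-0.038,2.99,3.49,0.50
age,>=65,,10.65,10.62,-0.030,3.22,3.52,0.31
citizenship,citizen,,10.65,10.61,-0.035,3.06,3.50,0.44
citizenship,non-citizen,,10.58,10.55,-0.034,3.18,3.57,0.39
education,primary,,10.61,10.58,-0.033,3.18,3.55,0.37
education,secondary,,10.64,10.60,-0.036,3.06,3.52,0.45
education,tertiary,,10.66,10.63,-0.038,3.04,3.52,0.48
employment,unemployed,,10.63,10.60,-0.036,3.08,3.51,0.43
employment,employed,,10.65,10.62,-0.036,3.01,3.49,0.48
income,bottom quintile,,10.57,10.53,-0.042,3.22,3.64,0.42
income,middle quintiles,,10.67,10.64,-0.034,2.80,3.31,0.51
income,top quintile,,10.69,10.67,-0.020,3.70,3.88,0.18
total,total,,10.64,10.61,-0.035,3.07,3.50,0.43
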
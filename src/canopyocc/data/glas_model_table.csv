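model,elev,fhd,home,can_height,hli,p_lower,p_mid,veg_density,julian_day,sky,df,logLik,AICc,delta,weight
160,-67.05,37.45,-98.89,203.13,-48.58,,,31.84,,,8,-66.60,151.45,0.00,0.177
224,-93.36,61.76,-157.13,285.28,-63.16,,-9.75,57.39,,,9,-65.85,152.56,1.11,0.101
382,-68.41,,-153.43,156.54,-77.74,-100.44,-2.72,,-0.33,,9,-65.97,152.79,1.34,0.090
928,-78.24,43.22,-114.44,236.73,-56.85,,,36.39,-0.36,-0.19,10,-64.69,152.92,1.47,0.085
672,-77.98,43.53,-115.08,236.15,-56.31,,,37.07,,-0.19,9,-66.16,153.17,1.72,0.075
221,,,-144.38,174.87,-66.23,,-78.37,76.93,,,7,-68.88,153.47,2.02,0.064
176,-147.04,107.85,-110.06,294.86,,69.83,,62.13,,,8,-68.05,154.35,2.90,0.041
894,-106.34,,-221.14,247.94,-119.19,-147.19,10.61,,-0.32,-0.20,10,-65.49,154.54,3.08,0.038
206,-68.28,,-135.07,132.80,,,-49.41,79.31,,,7,-69.64,155.01,3.55,0.030
477,,,-91.61,127.66,-41.94,,-45.09,41.18,-0.29,,8,-68.44,155.14,3.68,0.028
733,,,-177.87,216.25,-82.75,,-96.36,94.85,,-0.18,8,-68.46,155.16,3.71,0.028
192,-62.66,-15.09,-137.55,140.90,-82.43,-106.11,,-6.70,,,9,-67.31,155.47,4.02,0.024
448,-68.42,12.38,-135.16,178.96,-69.03,-64.18,,10.00,-0.33,,10,-65.97,155.50,4.04,0.023
736,-87.09,70.01,-209.57,296.30,-60.45,,-46.08,78.18,,-0.21,10,-66.02,155.59,4.14,0.022
223,,-33.28,-140.63,197.60,-104.06,,-78.12,63.89,,,8,-68.78,155.81,4.36,0.020
462,-51.77,,-103.44,101.11,,,-38.33,60.88,-0.28,,8,-68.79,155.83,4.38,0.020
992,-189.14,121.41,-364.00,606.65,-138.12,,-55.46,137.20,-0.32,-0.22,11,-64.77,155.87,4.42,0.019
989,,,-129.90,157.61,-59.85,,-70.45,69.10,-0.29,-0.19,9,-67.55,155.96,4.51,0.019
512,-89.08,41.11,-166.08,248.49,-72.57,-44.97,-1.72,37.27,-0.37,,11,-64.95,156.23,4.78,0.016
479,,-16.27,-132.75,175.36,-74.68,,-77.53,63.72,-0.29,,9,-67.75,156.36,4.90,0.015
16,-58.55,40.27,-52.28,88.17,,,,,,,6,-71.58,156.44,4.98,0.015
640,-76.42,2.10,-166.48,180.24,-84.73,-102.70,-3.51,,,-0.21,10,-66.75,157.04,5.59,0.011
704,-56.05,0.02,-107.61,137.96,-63.41,-64.87,,3.77,,-0.21,10,-66.79,157.13,5.68,0.010
718,-53.67,,-107.68,105.14,,,-39.86,63.27,,-0.15,8,-69.47,157.19,5.74,0.010
768,-62.97,30.52,-102.80,185.63,-49.88,-13.95,-1.48,28.47,,-0.19,11,-65.43,157.19,5.74,0.010
238,-50.93,,-102.06,107.28,,7.77,-41.17,63.69,,,8,-69.53,157.30,5.85,0.009
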
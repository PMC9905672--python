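bed,group,age_wk,n,ach_mean,ach_se,mvd_mean,mvd_se,beta_mean,beta_se,mass_mean,mass_se,insulin_mean,insulin_se,glucose_mean,glucose_se,tnf_mean,tnf_se,synthetic_fields
skeletal,LZR,7,51,119.2,1.1,809.9,13.9,2.6,0.1,149.7,1.5,1.0,0.1,93.7,1.1,100,5,tnf
skeletal,LZR,10,37,125.0,1.1,810.4,13.1,2.6,0.1,243.0,2.1,1.2,0.1,98.4,1.1,100,5,tnf
skeletal,LZR,13,44,129.3,1.2,811.8,11.9,2.8,0.1,307.2,2.0,1.3,0.1,100.9,1.1,100,5,tnf
skeletal,LZR,17,48,136.5,2.0,863.1,4.6,3.1,0.1,357.5,1.5,1.1,0.1,100.2,1.4,100,5,tnf
skeletal,LZR,20,6,139.9,1.6,823.0,9.1,3.2,0.1,374.3,2.6,1.5,0.1,104.7,2.0,100,5,tnf
skeletal,OZR,7,36,115.3,1.9,805.4,25.2,2.4,0.3,233.9,1.8,3.5,0.1,99.7,1.4,140,8,tnf
skeletal,OZR,10,30,118.4,3.2,782.4,26.1,3.4,0.5,409.4,2.6,5.0,0.1,118.6,3.4,160,8,tnf
skeletal,OZR,13,36,120.5,2.8,706.9,16.9,4.1,0.6,512.3,3.2,7.6,0.2,138.6,2.7,180,8,tnf
skeletal,OZR,17,28,122.6,2.9,656.3,20.5,6.2,0.4,682.3,2.5,7.8,0.1,179.1,1.2,195,8,tnf
skeletal,OZR,20,6,119.3,3.3,635.9,11.6,5.7,0.7,741.8,11.0,10.8,0.6,182.6,2.7,200,8,tnf
skeletal,OZR+HYD,7,4,117.6,2.6,881.4,10.8,3.7,0.3,244.0,3.9,3.9,0.1,101.0,1.8,132,8,tnf
skeletal,OZR+HYD,10,4,127.3,2.2,874.6,14.6,3.5,0.3,411.5,3.4,5.5,0.3,104.5,2.5,148,8,tnf
skeletal,OZR+HYD,13,5,131.7,2.3,832.3,21.5,3.8,0.4,510.4,9.2,8.1,0.3,134.2,3.8,164,8,tnf
skeletal,OZR+HYD,17,4,129.6,3.4,869.4,17.3,4.0,0.3,606.0,4.8,9.5,0.3,170.5,3.3,176,8,tnf
skeletal,OZR+CAP,7,10,118.3,2.7,833.3,12.3,3.2,0.2,239.0,2.7,3.5,0.2,99.0,3.5,120,8,tnf
skeletal,OZR+CAP,10,10,117.0,2.1,813.3,5.5,3.5,0.3,409.0,4.5,3.7,0.3,100.0,2.5,130,8,tnf
skeletal,OZR+CAP,13,10,124.8,3.9,764.0,8.0,4.2,0.2,515.3,4.6,5.4,0.3,123.5,2.5,140,8,tnf
skeletal,OZR+CAP,17,10,124.3,1.9,730.5,16.6,4.8,0.3,624.3,8.6,6.7,0.2,137.5,5.3,147.5,8,tnf
skeletal,OZR+GEM,7,10,125.5,3.1,830.2,16.5,3.0,0.1,257.0,4.3,4.4,0.2,100.9,2.6,132,8,tnf
skeletal,OZR+GEM,10,10,126.0,1.8,770.2,12.8,4.0,0.2,403.7,3.6,5.7,0.3,105.2,2.3,148,8,tnf
skeletal,OZR+GEM,13,10,122.1,2.9,688.0,11.6,5.7,0.3,514.4,4.7,7.3,0.3,126.0,3.5,164,8,tnf
skeletal,OZR+GEM,17,10,121.6,2.9,660.2,10.9,6.4,0.1,631.7,5.8,8.6,0.3,170.2,3.1,176,8,tnf
skeletal,OZR+ATOR,7,10,124.0,3.4,806.4,8.4,3.1,0.1,246.0,1.7,3.7,0.2,96.2,1.1,120,8,tnf
skeletal,OZR+ATOR,10,10,129.1,2.7,803.4,4.3,3.8,0.3,404.5,3.2,4.4,0.1,109.8,2.2,130,8,tnf
skeletal,OZR+ATOR,13,10,129.3,2.9,785.2,5.0,5.1,0.2,493.5,10.0,5.7,0.3,128.7,2.2,140,8,tnf
skeletal,OZR+ATOR,17,10,134.6,2.7,769.1,7.1,5.0,0.3,615.2,5.4,6.3,0.2,159.1,3.5,147.5,8,tnf
skeletal,OZR+TEM,7,4,113.8,4.8,839.0,6.2,3.4,0.6,233.0,3.6,3.4,0.3,97.5,4.1,120,8,tnf
skeletal,OZR+TEM,10,4,120.5,2.2,841.4,7.3,3.8,0.2,412.0,11.0,5.2,0.3,110.8,10.9,130,8,tnf
skeletal,OZR+TEM,13,4,119.5,5.6,850.2,9.6,4.4,0.2,525.5,9.2,8.1,0.5,134.3,5.5,140,8,tnf
skeletal,OZR+TEM,17,9,118.8,5.4,814.1,6.3,6.3,0.1,612.0,12.7,9.9,0.3,170.5,4.5,147.5,8,tnf
skeletal,OZR+PEN,7,4,113.8,4.8,839.0,6.2,3.4,0.6,233.9,1.8,3.5,0.1,99.7,1.4,120,8,ach mvd beta mass insulin glucose tnf
skeletal,OZR+PEN,10,4,120.5,2.2,841.4,7.3,3.8,0.2,409.4,2.6,5.0,0.1,118.6,3.4,130,8,ach mvd beta mass insulin glucose tnf
skeletal,OZR+PEN,17,4,118.8,5.4,814.1,6.3,6.3,0.1,682.3,2.5,7.8,0.1,179.1,1.2,147.5,8,ach mvd beta mass insulin glucose tnf
skeletal,OZR+LNM,7,4,99.3,4.3,833.3,7.8,3.4,0.2,238.5,5.1,3.9,0.2,95.5,1.7,150,8,tnf
skeletal,OZR+LNM,10,4,99.25,4.2,798.5,21.3,4.4,0.2,407.8,8.1,5.8,0.3,123.3,6.4,170,8,tnf
skeletal,OZR+LNM,13,4,109.5,6.3,722.3,12.0,5.5,0.3,501.0,3.8,9.9,0.2,149.5,3.9,190,8,tnf
skeletal,OZR+LNM,17,4,108.5,1.7,638.5,8.3,7.0,0.2,597.3,3.7,11.3,0.4,174.8,4.0,205,8,tnf
cerebral,LZR,7,36,135.2,1.3,290.0,1.9,1.6,0.1,149.7,1.5,1.0,0.1,93.7,1.1,100,5,tnf
cerebral,LZR,10,18,144.1,0.9,293.0,2.1,1.7,0.1,243.0,2.1,1.2,0.1,98.4,1.1,100,5,tnf
cerebral,LZR,13,24,151.8,0.8,303.8,1.2,1.8,0.1,307.2,2.0,1.3,0.1,100.9,1.1,100,5,tnf
cerebral,LZR,17,18,155.0,1.4,313.6,1.4,2.0,0.1,357.5,1.5,1.1,0.1,100.2,1.4,100,5,tnf
cerebral,LZR,20,19,163.0,1.1,319.6,1.0,2.2,0.1,374.3,2.6,1.5,0.1,104.7,2.0,100,5,tnf
cerebral,OZR,7,20,122.4,1.3,274.0,3.2,1.8,0.1,233.9,1.8,3.5,0.1,99.7,1.4,140,8,tnf
cerebral,OZR,10,8,128.4,1.0,270.1,2.6,2.1,0.1,409.4,2.6,5.0,0.1,118.6,3.4,160,8,tnf
cerebral,OZR,13,14,125.1,0.8,255.8,2.6,2.8,0.2,512.3,3.2,7.6,0.2,138.6,2.7,180,8,tnf
cerebral,OZR,17,12,122.9,1.7,249.1,2.1,4.0,0.2,682.3,2.5,7.8,0.1,179.1,1.2,195,8,tnf
cerebral,OZR,20,8,119.8,2.5,242.0,1.9,5.4,0.1,741.8,11.0,10.8,0.6,182.6,2.7,200,8,tnf
cerebral,OZR+HYD,7,6,117.6,2.6,341.0,3.0,3.7,0.3,244.0,3.9,3.9,0.1,101.0,1.8,132,8,tnf
cerebral,OZR+HYD,13,6,131.7,2.3,308.3,2.0,3.8,0.4,510.4,9.2,8.1,0.3,134.2,3.8,164,8,tnf
cerebral,OZR+HYD,17,6,129.6,3.4,279.7,2.1,4.0,0.3,606.0,4.8,9.5,0.3,170.5,3.3,176,8,tnf
cerebral,OZR+CAP,7,6,137.5,0.7,337.3,2.7,2.5,0.1,239.0,2.7,3.5,0.2,99.0,3.5,120,8,tnf
cerebral,OZR+CAP,13,6,139.0,0.7,332.0,1.7,3.3,0.1,515.3,4.6,5.4,0.3,123.5,2.5,140,8,tnf
cerebral,OZR+CAP,17,6,132.5,2.4,310.3,2.2,4.7,0.1,624.3,8.6,6.7,0.2,137.5,5.3,147.5,8,tnf
cerebral,OZR+MET,7,6,133.2,0.9,329.0,2.4,2.5,0.1,237.0,1.0,3.4,0.2,123.7,2.1,120,8,tnf
cerebral,OZR+MET,13,6,134.2,0.9,334.7,3.2,3.5,0.1,485.0,6.1,4.3,0.1,121.8,1.5,140,8,tnf
cerebral,OZR+MET,17,6,132.3,1.6,322.3,2.3,6.0,0.1,658.8,4.2,5.3,0.1,132.5,2.3,147.5,8,tnf
cerebral,OZR+ROSI,7,6,134.6,0.5,333.3,2.5,2.6,0.1,246.8,2.9,3.5,0.1,121.5,0.9,120,8,tnf
cerebral,OZR+ROSI,13,6,135.7,1.7,309.7,3.4,3.5,0.1,475.7,3.1,4.0,0.1,118.0,1.8,140,8,tnf
cerebral,OZR+ROSI,17,6,127.5,1.2,322.0,2.6,6.1,0.1,680.2,5.1,5.1,0.1,126.8,3.3,147.5,8,tnf
cerebral,OZR+TEM,7,6,135.3,0.3,341.7,1.2,2.5,0.1,233.0,3.6,3.4,0.3,97.5,4.1,120,8,tnf
cerebral,OZR+TEM,13,6,133.7,1.6,341.0,1.2,3.4,0.1,525.5,9.2,8.1,0.5,134.3,5.5,140,8,tnf
cerebral,OZR+TEM,17,6,134.2,1.6,333.3,2.8,5.6,0.1,612.0,12.7,9.9,0.3,170.5,4.5,147.5,8,tnf
cerebral,OZR+LNM,7,6,126.2,0.9,331.2,1.6,2.6,0.1,238.5,5.1,3.9,0.2,95.5,1.7,150,8,tnf
cerebral,OZR+LNM,13,6,117.3,2.5,305.0,1.8,4.5,0.1,501.0,3.8,9.9,0.2,149.5,3.9,190,8,tnf
cerebral,OZR+LNM,17,6,112.8,1.2,257.3,1.1,7.1,0.2,597.3,3.7,11.3,0.4,174.8,4.0,205,8,tnf
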